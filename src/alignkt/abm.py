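"""Agent-based simulator of aligning self-propelled particles.

Particles move ballistically at speed ``v0`` in a periodic square box while
their headings follow the additive alignment torque
``Gamma * sum_{j in Omega_i} sin(n (theta_j - theta_i))`` over metric
neighbours within radius ``R`` (no normalization by neighbour count), plus
rotational noise of strength ``Dr``.  Integration is an explicit
Euler--Maruyama scheme; positions advance with the pre-update heading.

Two engines consume the identical noise stream for the same seed and agree
to floating-point round-off: a plain numpy :func:`step` built on a periodic
k-d tree (the readable reference) and a compiled linked-cell loop
(:mod:`alignkt._simfast`) used by :func:`simulate` for long runs.  Each
engine on its own is bitwise reproducible given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model_core import ModelParams
from .modes import ModeSpectrum

__all__ = [
    "ParticleState",
    "Trajectory",
    "neighbor_pairs",
    "step",
    "init_wedge",
    "measure_modes",
    "bond_order",
    "simulate",
]

_TWO_PI = 2.0 * np.pi


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval ``(-pi, pi]``.

    Angles already in range are returned bit-identically (the modular
    reduction is skipped), so noise-free dynamics leave headings untouched.
    """
    theta = np.asarray(theta)
    wrapped = np.pi - (np.pi - theta) % _TWO_PI
    return np.where((theta > -np.pi) & (theta <= np.pi), theta, wrapped)


@dataclass
class ParticleState:
    """Positions, unwrapped positions, headings and time of the ensemble."""

    positions: np.ndarray          # (N, 2), wrapped to [0, L)^2
    unwrapped_positions: np.ndarray  # (N, 2), no wrapping (for MSD)
    angles: np.ndarray             # (N,), wrapped to (-pi, pi]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.unwrapped_positions = np.ascontiguousarray(
            self.unwrapped_positions, dtype=float)
        self.angles = np.ascontiguousarray(self.angles, dtype=float)
        n = len(self.angles)
        if self.positions.shape != (n, 2) or self.unwrapped_positions.shape != (n, 2):
            raise ValueError("positions and angles have inconsistent shapes")

    @property
    def N(self) -> int:
        return len(self.angles)

    def validate(self, params: ModelParams) -> None:
        if self.N != params.N:
            raise ValueError(f"state has {self.N} particles, params say {params.N}")
        if np.any(self.positions < 0) or np.any(self.positions >= params.L):
            raise ValueError("wrapped positions outside [0, L)^2")
        if np.any(self.angles <= -np.pi) or np.any(self.angles > np.pi):
            raise ValueError("angles outside (-pi, pi]")
        # unwrapped and wrapped agree modulo L
        if not np.allclose(self.unwrapped_positions % params.L, self.positions,
                           atol=1e-8 * params.L):
            raise ValueError("unwrapped positions inconsistent with wrapped ones")

    def copy(self) -> "ParticleState":
        return ParticleState(self.positions.copy(), self.unwrapped_positions.copy(),
                             self.angles.copy(), self.time)


def neighbor_pairs(state: ParticleState, params: ModelParams) -> np.ndarray:
    """Interacting pairs ``(i, j)`` with ``i < j`` under the minimum-image metric.

    A pair is present iff the periodic distance is ``<= R``.  Requires
    ``R <= L/2`` for the minimum-image convention to be well defined.
    """
    if params.R > params.L / 2:
        raise ValueError(f"R={params.R} exceeds L/2={params.L / 2}; "
                         "minimum-image neighborhood ill-defined")
    tree = cKDTree(state.positions, boxsize=params.L)
    pairs = tree.query_pairs(params.R, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order].astype(np.int64)


def _torques(state: ParticleState, params: ModelParams) -> np.ndarray:
    pairs = neighbor_pairs(state, params)
    torque = np.zeros(state.N)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        s = params.Gamma * np.sin(params.n * (state.angles[j] - state.angles[i]))
        np.add.at(torque, i, s)
        np.add.at(torque, j, -s)
    return torque


def _accuracy_warning(params: ModelParams) -> None:
    if abs(params.Gamma) * params.M * params.dt > 0.1:
        warnings.warn(
            f"|Gamma|*M*dt = {abs(params.Gamma) * params.M * params.dt:.3g} > 0.1: "
            "the Euler step may be inaccurate", stacklevel=3)


def step(state: ParticleState, params: ModelParams,
         rng: np.random.Generator | None = None,
         move_with_updated_heading: bool = False) -> ParticleState:
    """One explicit Euler--Maruyama step; returns a new state.

    Torques and displacements are evaluated at the pre-step state; the noise
    increment is ``sqrt(2 Dr dt)`` times independent standard normals, drawn
    in particle order from ``rng`` (required when ``Dr > 0``).
    """
    _accuracy_warning(params)
    torque = _torques(state, params)
    theta_new = state.angles + params.dt * torque
    if params.Dr > 0:
        if rng is None:
            raise ValueError("Dr > 0 requires a random generator")
        theta_new = theta_new + np.sqrt(2 * params.Dr * params.dt) * \
            rng.standard_normal(state.N)
    theta_new = wrap_angle(theta_new)
    th_move = theta_new if move_with_updated_heading else state.angles
    disp = params.v0 * params.dt * np.column_stack(
        (np.cos(th_move), np.sin(th_move)))
    return ParticleState(
        positions=(state.positions + disp) % params.L,
        unwrapped_positions=state.unwrapped_positions + disp,
        angles=theta_new,
        time=state.time + params.dt,
    )


def init_wedge(params: ModelParams, alpha: float,
               rng: np.random.Generator) -> ParticleState:
    """Polarized spatially uniform initial condition.

    Positions are independent uniform on ``[0, L)^2`` and headings uniform on
    ``[-alpha/2, alpha/2]``; the ensemble is polarized along the x axis, so
    ensemble-averaged Fourier modes are real.
    """
    if not 0 < alpha <= _TWO_PI:
        raise ValueError(f"alpha must be in (0, 2*pi], got {alpha}")
    pos = rng.uniform(0.0, params.L, size=(params.N, 2))
    theta = wrap_angle(rng.uniform(-alpha / 2, alpha / 2, size=params.N))
    return ParticleState(pos, pos.copy(), theta, 0.0)


def measure_modes(state: ParticleState, m_max: int) -> ModeSpectrum:
    """Empirical angular Fourier modes ``phat_m = (1/2N) sum_i exp(-i m theta_i)``.

    The 1/(2N) normalization matches the kinetic theory's density mode
    ``phat_0 = 1/2`` exactly; negative modes follow by conjugation.
    """
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    m = np.arange(m_max + 1)
    coeff = np.exp(-1j * np.outer(m, state.angles)).sum(axis=1) / (2 * state.N)
    coeff[0] = 0.5
    return ModeSpectrum(coeff)


def bond_order(state: ParticleState, l: int) -> complex:
    """Per-particle bond order parameter ``m_l = (1/N) sum_i exp(i l theta_i)``.

    Normalized per particle so that ``|m_l| <= 1`` (the unnormalized sum is
    just ``N`` times this value).
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    return complex(np.exp(1j * l * state.angles).mean())


@dataclass
class Trajectory:
    """Sampled records of a simulation run.

    ``times`` holds the raw-unit sampling times; ``angles`` (S, N), ``modes``
    (S, m_max+1) and ``unwrapped`` (S, N, 2) are present according to the
    ``record`` selection passed to :func:`simulate`.
    """

    params: ModelParams
    times: np.ndarray
    seed: int | None = None
    angles: np.ndarray | None = None
    modes: np.ndarray | None = None
    positions: np.ndarray | None = None
    unwrapped: np.ndarray | None = None
    m_max: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def times_rescaled(self) -> np.ndarray:
        """Sampling times in rescaled units (R = v0 = 1)."""
        return self.params.to_rescaled_time(self.times)

    @property
    def times_scaled(self) -> np.ndarray:
        """Scaled time ``t' = Sc * t`` (rescaled units)."""
        return self.params.Sc * self.times_rescaled

    def save(self, path: str | Path) -> None:
        """Write the trajectory to an HDF5 file (groups /params, /times, ...)."""
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("params")
            for k in ("N", "L", "R", "v0", "Gamma", "Dr", "n", "dt"):
                g.attrs[k] = getattr(self.params, k)
            if self.seed is not None:
                g.attrs["seed"] = self.seed
            f.create_dataset("times", data=self.times)
            for name in ("angles", "modes", "positions", "unwrapped"):
                data = getattr(self, name)
                if data is not None:
                    f.create_dataset(name, data=data)


def _numba_available() -> bool:
    try:
        from . import _simfast  # noqa: F401
        return True
    except Exception:  # pragma: no cover - import failure path
        return False


def simulate(params: ModelParams, initial: ParticleState, t_end: float,
             rng: np.random.Generator | None = None, *,
             record: tuple[str, ...] = ("modes",), stride: int = 1,
             m_max: int = 10, engine: str = "auto", seed: int | None = None,
             move_with_updated_heading: bool = False) -> Trajectory:
    """Integrate the model to ``t_end`` and record observables every ``stride`` steps.

    ``record`` may contain ``"modes"``, ``"angles"``, ``"positions"`` and
    ``"unwrapped"``; the initial state is always the first record.  Runs are
    bitwise deterministic given the generator state and engine; the two
    engines consume the identical noise stream and agree to round-off.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if params.R > params.L / 2:
        raise ValueError("R must be <= L/2")
    _accuracy_warning(params)
    n_steps = int(round(t_end / params.dt))
    if engine == "auto":
        engine = "numba" if _numba_available() else "numpy"
    if params.Dr > 0 and rng is None:
        raise ValueError("Dr > 0 requires a random generator")

    state = initial.copy()
    n_rec = n_steps // stride + 1 + (1 if n_steps % stride else 0)
    times = np.empty(n_rec)
    rec_angles = np.empty((n_rec, params.N)) if "angles" in record else None
    rec_modes = np.empty((n_rec, m_max + 1), dtype=complex) \
        if "modes" in record else None
    rec_pos = np.empty((n_rec, params.N, 2)) if "positions" in record else None
    rec_upos = np.empty((n_rec, params.N, 2)) if "unwrapped" in record else None

    def _record(k: int) -> None:
        times[k] = state.time
        if rec_angles is not None:
            rec_angles[k] = state.angles
        if rec_modes is not None:
            rec_modes[k] = measure_modes(state, m_max).coefficients
        if rec_pos is not None:
            rec_pos[k] = state.positions
        if rec_upos is not None:
            rec_upos[k] = state.unwrapped_positions

    _record(0)
    sigma = np.sqrt(2 * params.Dr * params.dt)
    if engine == "numba":
        from ._simfast import advance

        done = 0
        k = 1
        t0 = state.time
        while done < n_steps:
            chunk = min(stride, n_steps - done)
            if sigma > 0:
                noise = rng.standard_normal((chunk, params.N))
            else:
                noise = np.empty((0, params.N))
            advance(state.positions, state.unwrapped_positions, state.angles,
                    noise, chunk, params.L, params.R, params.v0, params.Gamma,
                    params.n, params.dt, sigma, move_with_updated_heading)
            done += chunk
            state.time = t0 + done * params.dt
            if done % stride == 0 or done == n_steps:
                _record(k)
                k += 1
    elif engine == "numpy":
        k = 1
        for s in range(1, n_steps + 1):
            state = step(state, params, rng,
                         move_with_updated_heading=move_with_updated_heading)
            if s % stride == 0 or s == n_steps:
                _record(k)
                k += 1
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return Trajectory(params=params, times=times[:k], seed=seed,
                      angles=None if rec_angles is None else rec_angles[:k],
                      modes=None if rec_modes is None else rec_modes[:k],
                      positions=None if rec_pos is None else rec_pos[:k],
                      unwrapped=None if rec_upos is None else rec_upos[:k],
                      m_max=m_max if rec_modes is not None else None)
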