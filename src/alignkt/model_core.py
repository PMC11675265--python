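"""Parameters and unit conventions for the aligning self-propelled particle model.

The microscopic model is a continuous-time Vicsek-like system: ``N`` point
particles in a periodic square box of edge ``L`` move at fixed speed ``v0``
along their heading angle, while the heading of particle ``i`` relaxes under
the additive torque ``Gamma * sum_j sin(n * (theta_j - theta_i))`` over all
neighbours within the interaction radius ``R``, plus rotational white noise of
strength ``Dr``.  The integer ``n`` (the *chelation number*) sets the symmetry
of the alignment: ``n=1`` polar, ``n=2`` nematic, ``n=3`` triatic.

Three dimensionless groups control the physics:

- ``M = pi R^2 N / L^2`` -- mean number of particles inside one interaction
  disk (dimensionless density),
- ``Sc = Gamma R / v0`` -- dimensionless coupling,
- ``Pe = v0 / (R Dr)`` -- Peclet number; its inverse is the dimensionless
  noise strength (``Pe_inv = 0`` is the deterministic system).

All kinetic-theory quantities in :mod:`alignkt.kinetic` are expressed in
rescaled units ``R = v0 = 1`` (time measured in units of ``R / v0``); this
module centralizes the conversion between raw simulation units and those
rescaled units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

__all__ = ["ModelParams", "make_params", "load_config", "save_config"]

#: exact key set used in configuration files
_CONFIG_KEYS = (
    "n_particles",
    "box_length",
    "density_M",
    "radius",
    "speed",
    "gamma",
    "d_rot",
    "chelation",
    "dt",
    "seed",
)


class ParameterError(ValueError):
    """Raised when a model parameter violates its constraint; names the field."""


@dataclass(frozen=True)
class ModelParams:
    """Immutable microscopic parameter set with derived dimensionless groups.

    Attributes
    ----------
    N : int
        Particle count, ``>= 1``.
    L : float
        Box edge length (same length unit as ``R``).
    R : float
        Interaction radius.
    v0 : float
        Propulsion speed.
    Gamma : float
        Alignment strength (1/time); negative values are anti-aligning.
    Dr : float
        Rotational diffusion constant (1/time), ``>= 0``.
    n : int
        Chelation number: symmetry order of the alignment kernel.
    dt : float
        Euler integration time step.
    """

    N: int
    L: float
    R: float
    v0: float
    Gamma: float
    Dr: float
    n: int
    dt: float

    def __post_init__(self) -> None:
        if not isinstance(self.N, (int,)) or self.N < 1:
            raise ParameterError(f"N must be an integer >= 1, got {self.N!r}")
        if not isinstance(self.n, (int,)) or self.n < 1:
            raise ParameterError(f"n must be an integer >= 1, got {self.n!r}")
        for name in ("L", "R", "v0", "dt"):
            val = getattr(self, name)
            if not val > 0:
                raise ParameterError(f"{name} must be > 0, got {val!r}")
        if self.Dr < 0:
            raise ParameterError(f"Dr must be >= 0, got {self.Dr!r}")

    # ---- derived dimensionless groups ------------------------------------

    @property
    def M(self) -> float:
        """Dimensionless density ``pi R^2 N / L^2``."""
        return math.pi * self.R**2 * self.N / self.L**2

    @property
    def Sc(self) -> float:
        """Dimensionless coupling ``Gamma R / v0``."""
        return self.Gamma * self.R / self.v0

    @property
    def Pe_inv(self) -> float:
        """Inverse Peclet number ``R Dr / v0`` (0 for the deterministic system)."""
        return self.R * self.Dr / self.v0

    @property
    def gamma_eff(self) -> float:
        """Effective interaction strength ``gamma = Sc * M``."""
        return self.Sc * self.M

    @property
    def MSc2(self) -> float:
        """``M * Sc^2``, the scale of the beyond-mean-field (Landau) terms."""
        return self.M * self.Sc**2

    # ---- unit conversion (raw <-> rescaled R = v0 = 1) -------------------

    def to_rescaled_time(self, t: Any) -> Any:
        """Convert a raw-unit time to rescaled units (multiply by ``v0/R``)."""
        return t * self.v0 / self.R

    def from_rescaled_time(self, t: Any) -> Any:
        """Convert a rescaled-unit time back to raw units."""
        return t * self.R / self.v0

    def to_rescaled_diffusivity(self, D: Any) -> Any:
        """Convert a raw-unit diffusivity (length^2/time) to rescaled units."""
        return D / (self.R * self.v0)

    def scaled_time(self, t: Any) -> Any:
        """Scaled time ``t' = Sc * t`` with ``t`` in raw units."""
        return self.Sc * self.to_rescaled_time(t)


def make_params(
    *,
    N: int,
    R: float = 1.0,
    v0: float = 1.0,
    Gamma: float = 0.0,
    Dr: float = 0.0,
    n: int = 1,
    dt: float = 0.01,
    L: float | None = None,
    M: float | None = None,
) -> ModelParams:
    """Build a :class:`ModelParams`, fixing the box by either ``L`` or ``M``.

    Exactly one of ``L`` (box edge) or ``M`` (dimensionless density) must be
    given; supplying ``M`` sets ``L = sqrt(pi R^2 N / M)``.

    Raises
    ------
    ParameterError
        If both or neither of ``L``/``M`` are supplied, or if any positivity
        or integrality constraint is violated (the message names the field).
    """
    if (L is None) == (M is None):
        raise ParameterError("exactly one of L or M must be supplied")
    if L is None:
        if not M > 0:
            raise ParameterError(f"M must be > 0, got {M!r}")
        L = math.sqrt(math.pi * R**2 * N / M)
    return ModelParams(N=int(N), L=float(L), R=float(R), v0=float(v0),
                       Gamma=float(Gamma), Dr=float(Dr), n=int(n), dt=float(dt))


# ---- configuration files -------------------------------------------------


def save_config(params: ModelParams, path: str | Path, seed: int | None = None) -> None:
    """Write a JSON or TOML configuration file (by extension) for ``params``.

    Both ``box_length`` and the redundant ``density_M`` are written; the
    loader checks their consistency.
    """
    cfg = {
        "n_particles": params.N,
        "box_length": params.L,
        "density_M": params.M,
        "radius": params.R,
        "speed": params.v0,
        "gamma": params.Gamma,
        "d_rot": params.Dr,
        "chelation": params.n,
        "dt": params.dt,
        "seed": seed,
    }
    path = Path(path)
    if path.suffix == ".toml":
        lines = []
        for k in _CONFIG_KEYS:
            v = cfg[k]
            if v is None:
                continue
            lines.append(f"{k} = {v!r}" if isinstance(v, str) else f"{k} = {v}")
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps(cfg, indent=2) + "\n")


def load_config(path: str | Path) -> tuple[ModelParams, int | None]:
    """Read a JSON or TOML configuration file; returns ``(params, seed)``."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        cfg = tomllib.loads(path.read_text())
    else:
        cfg = json.loads(path.read_text())
    unknown = set(cfg) - set(_CONFIG_KEYS)
    if unknown:
        raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
    if "n_particles" not in cfg:
        raise ParameterError("n_particles is required")
    L = cfg.get("box_length")
    M = cfg.get("density_M")
    if L is None and M is None:
        raise ParameterError("one of box_length or density_M is required")
    kwargs = dict(
        N=int(cfg["n_particles"]),
        R=float(cfg.get("radius", 1.0)),
        v0=float(cfg.get("speed", 1.0)),
        Gamma=float(cfg.get("gamma", 0.0)),
        Dr=float(cfg.get("d_rot", 0.0)),
        n=int(cfg.get("chelation", 1)),
        dt=float(cfg.get("dt", 0.01)),
    )
    if L is not None:
        params = make_params(L=float(L), **kwargs)
        if M is not None and not math.isclose(params.M, float(M), rel_tol=1e-6):
            raise ParameterError(
                f"box_length and density_M are inconsistent: M={params.M} vs {M}"
            )
    else:
        params = make_params(M=float(M), **kwargs)
    seed = cfg.get("seed")
    return params, (None if seed is None else int(seed))
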