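"""Self-diffusion of aligning self-propelled particles.

At anti-aligning coupling (or with rotational noise) the headings decorrelate
and the ballistic particles become diffusive at long times ("self-mixing").
The kinetic theory predicts the heading correlation time from the coupling of
a tracer's velocity mode to the background density: the only matrix element
that survives in the unordered background is the Landau element ``K_{1,0}``,
which has no mean-field counterpart, giving (rescaled units, zero noise)

    D_self = -1 / K10,   tau_c = 2 D_self,

with ``K10 = L_{1,0} = -(16/(3 pi^2)) M Sc^2 sum_{j=1..2n} 1/(2j-1)`` in the
density normalization (``phat_0 = 1/2``) validated against simulation.  The
velocity autocorrelation function (VACF) decays as ``exp(-tau/tau_c)`` and
the mean squared displacement grows as ``4 D_self tau`` (standard
two-dimensional Green--Kubo normalization; the raw MSD slope is reported
alongside).  Empirical estimators for both routes operate on recorded
trajectories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .abm import Trajectory
from .kinetic import landau_kernel_integral
from .model_core import ModelParams

__all__ = ["DiffusionResult", "theory_dself", "vacf", "fit_tau_c", "dself_msd"]


@dataclass
class DiffusionResult:
    """Self-diffusion constant with provenance and fit diagnostics.

    ``D_self`` and ``tau_c`` are in rescaled units (R = v0 = 1).  ``raw_rate``
    carries the un-normalized MSD slope ``<dr^2>/tau`` where applicable.
    """

    D_self: float
    tau_c: float
    method: str                      # theory | vacf_fit | msd_slope
    fit_window: tuple[float, float] | None = None
    stderr: float = math.nan
    raw_rate: float | None = None
    diagnostics: dict = field(default_factory=dict)


def theory_dself(params: ModelParams, convention: str = "A") -> DiffusionResult:
    """Kinetic-theory self-diffusion constant from the Landau element ``K10``.

    The Vlasov part of ``K_{1,0}`` vanishes for any ``n >= 1``, so
    ``K10 = L_{1,0} = (4/(3 pi^2)) M Sc^2 I(n, 1, 0)`` by quadrature (density
    normalization).  Two parses of the noisy-case formula are provided:
    convention ``A`` (default) adds the rates, ``D = -1/(K10 - Pe_inv)``;
    convention ``B`` reads ``D = -1/K10 - Pe_inv``.  Both coincide at
    ``Pe_inv = 0`` where ``D = -1/K10``.
    """
    K10 = 4.0 / (3.0 * math.pi**2) * params.MSc2 * \
        landau_kernel_integral(params.n, 1, 0)
    Pe_inv = params.Pe_inv
    if K10 >= 0 and Pe_inv == 0:
        raise ValueError("no mixing: K10 >= 0 and Pe_inv = 0, "
                         "the heading never decorrelates and D is undefined")
    if convention == "A":
        D = -1.0 / (K10 - Pe_inv)
    elif convention == "B":
        D = -1.0 / K10 - Pe_inv
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return DiffusionResult(D_self=D, tau_c=2 * D, method="theory",
                           diagnostics={"K10": K10, "Pe_inv": Pe_inv,
                                        "convention": convention})


def _angle_series(traj: Trajectory) -> tuple[np.ndarray, float]:
    if traj.angles is None:
        raise ValueError("trajectory has no recorded angles")
    dts = np.diff(traj.times)
    if len(dts) < 1 or not np.allclose(dts, dts[0], rtol=1e-8):
        raise ValueError("vacf requires a uniform recording stride")
    return traj.angles, float(dts[0])


def vacf(traj: Trajectory, lags: np.ndarray | None = None,
         t_start: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Velocity autocorrelation ``C(tau) = <v(t+tau).v(t)>/v0^2``.

    Averaged over particles and time origins after ``t_start`` (to discard a
    non-stationary transient); C(0) = 1 by normalization.  Returns
    ``(tau_raw_units, C)`` for the requested integer lags (default: up to a
    quarter of the record).
    """
    angles, dt_rec = _angle_series(traj)
    sel = traj.times >= t_start
    angles = angles[sel]
    S = len(angles)
    if S < 2:
        raise ValueError("fewer than 2 samples available for the VACF")
    if lags is None:
        lags = np.arange(S // 4 + 1)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= S):
        raise ValueError("lags out of range")
    # v(t+tau).v(t)/v0^2 = cos(theta(t+tau) - theta(t)) = Re e^{i th(t+tau)} e^{-i th(t)}
    e = np.exp(1j * angles)                      # (S, N)
    nfft = 1 << int(np.ceil(np.log2(2 * S)))
    F = np.fft.fft(e, n=nfft, axis=0)
    ac = np.fft.ifft(F * F.conjugate(), axis=0).real[:S]   # sum over origins
    counts = S - np.arange(S)
    C_all = ac.sum(axis=1) / (counts * e.shape[1])
    C = C_all[lags]
    return lags * dt_rec, C


def fit_tau_c(tau: np.ndarray, C: np.ndarray,
              window: tuple[float, float] = (0.1, 0.9)) -> DiffusionResult:
    """Correlation time from a weighted log-linear fit of an exponential VACF.

    Fits ``log C = log C0 - tau/tau_c`` over the lags where ``C`` lies inside
    ``window`` (weights proportional to ``C^2``, the inverse variance of the
    log-transform), then ``D_self = tau_c / 2``.  ``tau`` must be in rescaled
    units for the result to be comparable with theory.
    """
    tau = np.asarray(tau, dtype=float)
    C = np.asarray(C, dtype=float)
    sel = (C > window[0]) & (C < window[1]) & (tau > 0)
    if sel.sum() < 3:
        # shrink: accept anything positive and decaying below 1
        sel = (C > 0) & (C < 1.0 - 1e-12) & (tau > 0)
    if sel.sum() < 3:
        raise ValueError("no usable decay window in the correlation series")
    x = tau[sel]
    y = np.log(C[sel])
    wgt = C[sel] ** 2
    W = np.sum(wgt)
    xm = np.sum(wgt * x) / W
    ym = np.sum(wgt * y) / W
    sxx = np.sum(wgt * (x - xm) ** 2)
    slope = np.sum(wgt * (x - xm) * (y - ym)) / sxx
    if slope >= 0:
        raise ValueError("correlation series does not decay")
    resid = y - (ym + slope * (x - xm))
    dof = max(sel.sum() - 2, 1)
    slope_err = math.sqrt(np.sum(wgt * resid**2) / dof / sxx)
    tau_c = -1.0 / slope
    tau_c_err = slope_err * tau_c**2
    return DiffusionResult(D_self=tau_c / 2, tau_c=tau_c, method="vacf_fit",
                           fit_window=(float(x.min()), float(x.max())),
                           stderr=tau_c_err / 2,
                           diagnostics={"n_points": int(sel.sum())})


def dself_msd(traj: Trajectory, fit_window: tuple[float, float] | None = None,
              tau_c_estimate: float | None = None) -> DiffusionResult:
    """Self-diffusion constant from the mean-squared-displacement slope.

    ``MSD(tau) = <|x(t+tau) - x(t)|^2>`` is averaged over particles and time
    origins from unwrapped positions; the slope over ``fit_window`` (raw
    time units; default the upper half of available lags) gives
    ``D_self = slope / 4`` in two dimensions.  The raw defining rate
    ``MSD/tau`` (no 1/4) is reported as ``raw_rate``.  Warns when the window
    is shorter than ten correlation times or when the MSD still grows
    super-linearly (ballistic regime).
    """
    if traj.unwrapped is None:
        raise ValueError("trajectory has no recorded unwrapped positions")
    times = traj.times
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-8):
        raise ValueError("msd requires a uniform recording stride")
    dt_rec = float(dts[0])
    S = len(times)
    max_lag = S - 1
    lags = np.unique(np.round(np.geomspace(1, max_lag, 60)).astype(int))
    u = traj.unwrapped                           # (S, N, 2)
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = u[lag:] - u[:-lag]
        msd[k] = np.mean(np.sum(d * d, axis=-1))
    tau = lags * dt_rec

    if fit_window is None:
        fit_window = (tau[-1] / 2, tau[-1])
    sel = (tau >= fit_window[0]) & (tau <= fit_window[1])
    if sel.sum() < 3:
        raise ValueError("fit window contains fewer than 3 MSD points")
    if tau_c_estimate is not None and \
            fit_window[1] - fit_window[0] < 10 * tau_c_estimate:
        warnings.warn("MSD fit window shorter than 10 correlation times; "
                      "the slope may be biased", stacklevel=2)
    # local log-log exponent over the window: ~1 diffusive, ~2 ballistic
    expo = np.polyfit(np.log(tau[sel]), np.log(msd[sel]), 1)[0]
    if expo > 1.5:
        warnings.warn(f"MSD exponent {expo:.2f} > 1.5 in the fit window: "
                      "trajectory looks ballistic, no diffusive plateau",
                      stacklevel=2)
    A = np.column_stack((tau[sel], np.ones(sel.sum())))
    coef, res, *_ = np.linalg.lstsq(A, msd[sel], rcond=None)
    slope = float(coef[0])
    dof = max(sel.sum() - 2, 1)
    resvar = float(res[0]) / dof if len(res) else 0.0
    slope_err = math.sqrt(resvar / np.sum((tau[sel] - tau[sel].mean()) ** 2))
    # convert slope (raw units) to rescaled diffusivity
    p = traj.params
    D = p.to_rescaled_diffusivity(slope / 4)
    return DiffusionResult(D_self=D, tau_c=2 * D, method="msd_slope",
                           fit_window=fit_window,
                           stderr=p.to_rescaled_diffusivity(slope_err / 4),
                           raw_rate=slope,
                           diagnostics={"exponent": float(expo),
                                        "msd_tau": tau, "msd": msd})
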