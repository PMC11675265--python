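"""Truncated angular Fourier spectra of the one-particle distribution.

The one-particle angular distribution ``p(theta)`` is expanded as
``p(theta) = sum_m phat_m exp(i m theta)`` with
``phat_m = (1/2pi) int exp(-i m theta) p(theta) dtheta``.  The normalization
is fixed so that the density mode is ``phat_0 = 1/2``; since ``p`` is real,
``phat_{-m} = conj(phat_m)`` and only ``m >= 0`` is stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModeSpectrum"]


@dataclass
class ModeSpectrum:
    """Complex Fourier modes ``phat_m`` for ``m = 0..m_max``.

    Indexing with a negative ``m`` returns the complex conjugate of
    ``phat_{-m}``; indices outside the truncation raise ``IndexError``.
    """

    coefficients: np.ndarray
    m_max: int = field(init=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.coefficients.ndim != 1 or len(self.coefficients) < 1:
            raise ValueError("coefficients must be a 1-d array of length m_max+1")
        self.m_max = len(self.coefficients) - 1

    def __getitem__(self, m: int) -> complex:
        if abs(m) > self.m_max:
            raise IndexError(f"mode {m} outside truncation m_max={self.m_max}")
        c = self.coefficients[abs(m)]
        return complex(c.conjugate()) if m < 0 else complex(c)

    def validate(self, tol: float = 1e-9) -> None:
        """Check the density normalization ``phat_0 = 1/2`` and ``|phat_m| <= 1/2``."""
        if abs(self.coefficients[0] - 0.5) > tol:
            raise ValueError(f"phat_0 = {self.coefficients[0]} != 1/2")
        mods = np.abs(self.coefficients)
        if np.any(mods > 0.5 + tol):
            m = int(np.argmax(mods))
            raise ValueError(f"|phat_{m}| = {mods[m]} exceeds the density bound 1/2")

    # ---- canonical initial spectra --------------------------------------

    @classmethod
    def isotropic(cls, m_max: int) -> "ModeSpectrum":
        """Unordered state: only the density mode ``phat_0 = 1/2``."""
        c = np.zeros(m_max + 1, dtype=complex)
        c[0] = 0.5
        return cls(c)

    @classmethod
    def delta(cls, m_max: int, theta0: float = 0.0) -> "ModeSpectrum":
        """All particles at angle ``theta0``: ``phat_m = exp(-i m theta0)/2``."""
        m = np.arange(m_max + 1)
        return cls(0.5 * np.exp(-1j * m * theta0))

    @classmethod
    def wedge(cls, m_max: int, alpha: float) -> "ModeSpectrum":
        """Angles uniform on ``[-alpha/2, alpha/2]``: ``phat_m = sin(m alpha/2)/(m alpha)``.

        This is the exact ensemble spectrum of the polarized initial condition
        used in the theory-vs-simulation comparison; all modes are real.
        """
        if not 0 < alpha <= 2 * math.pi:
            raise ValueError(f"alpha must be in (0, 2*pi], got {alpha}")
        c = np.empty(m_max + 1, dtype=complex)
        c[0] = 0.5
        for m in range(1, m_max + 1):
            c[m] = math.sin(m * alpha / 2) / (m * alpha)
        return cls(c)
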