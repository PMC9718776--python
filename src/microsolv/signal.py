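"""From populations to ion yields.

The three measured mass channels are linear combinations of the
probe-convolved populations ``rho'_ii(t) = f(t) (x) rho_ii(t)``, where
``f`` is the area-normalised Gaussian intensity envelope of the NIR
probe (FWHM 70 fs by default):

    I_parent(t)   = p_parent(t)   * sum_{i=2..4} A_i rho'_ii(t)
    I_fragment(t) = p_fragment(t) * sum_{i=2..5} B_i rho'_ii(t)
    I_water(t)    = C rho'_55(t)

The parent (cluster ion) and fragment (bare chromophore ion) channels
carry a low-frequency intermolecular-vibration modulation
``p_j(t) = a_j + b_j cos(omega t + phi)`` with shared frequency and
phase; the water channel does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .constants import fwhm_to_sigma, FS_PER_PS
from .exceptions import (
    ExtrapolationError,
    GridResolutionError,
    ParameterError,
)
from .kinetics import DensityMatrixTrace

__all__ = [
    "CHANNELS",
    "OscillationParams",
    "SignalCoefficients",
    "IonYieldCurve",
    "convolve_probe",
    "model_ion_yields",
]

#: canonical channel labels: parent = indole(H2O)+, fragment = indole+,
#: water = H2O+
CHANNELS = ("parent", "fragment", "water")


@dataclass(frozen=True)
class OscillationParams:
    """Fixed cosine modulation of the parent and fragment channels.

    ``p_j(t) = a_j + b_j cos(omega t + phi)`` with one (a, b) pair per
    oscillating channel and shared angular frequency (rad/ps) and phase.
    Positivity of the modulation requires ``a_j > |b_j|``.
    """

    a_parent: float = 1.04
    b_parent: float = 0.14
    a_fragment: float = 0.92
    b_fragment: float = 0.11
    omega_rad_per_ps: float = 3.77
    phi: float = 1.77

    def __post_init__(self) -> None:
        if not self.a_parent > abs(self.b_parent):
            raise ParameterError("parent modulation must stay positive (a > |b|)")
        if not self.a_fragment > abs(self.b_fragment):
            raise ParameterError("fragment modulation must stay positive (a > |b|)")
        if self.omega_rad_per_ps < 0:
            raise ParameterError("omega must be non-negative")

    @property
    def period_ps(self) -> float:
        """Oscillation period 2 pi / omega (ps)."""
        return 2.0 * math.pi / self.omega_rad_per_ps

    def modulation(self, t_ps, channel: str) -> np.ndarray:
        """Evaluate p_channel(t); water is unmodulated (identically 1)."""
        t = np.asarray(t_ps, dtype=float)
        if channel == "parent":
            a, b = self.a_parent, self.b_parent
        elif channel == "fragment":
            a, b = self.a_fragment, self.b_fragment
        elif channel == "water":
            return np.ones_like(t)
        else:
            raise ParameterError(f"unknown channel {channel!r}")
        return a + b * np.cos(self.omega_rad_per_ps * t + self.phi)


@dataclass(frozen=True)
class SignalCoefficients:
    """Non-negative weights of the populations in each ion channel."""

    A2: float = 1.0
    A3: float = 0.22
    A4: float = 0.22
    B2: float = 0.05
    B3: float = 0.60
    B4: float = 0.15
    B5: float = 1.0
    C: float = 1.0

    def __post_init__(self) -> None:
        for name in ("A2", "A3", "A4", "B2", "B3", "B4", "B5", "C"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"coefficient {name} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.A2, self.A3, self.A4, self.B2, self.B3, self.B4, self.B5, self.C]
        )


@dataclass
class IonYieldCurve:
    """Delay-dependent yield of one mass channel with 1-sigma errors."""

    delays_ps: np.ndarray
    yields: np.ndarray
    sigma: np.ndarray | None = None
    channel: str = "parent"

    def __post_init__(self) -> None:
        self.delays_ps = np.asarray(self.delays_ps, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.delays_ps.shape:
                raise ParameterError("sigma must match delays in shape")
        if self.yields.shape != self.delays_ps.shape:
            raise ParameterError("yields must match delays in shape")
        if np.any(np.diff(self.delays_ps) <= 0):
            raise ParameterError("delays must be strictly increasing")

    def __len__(self) -> int:
        return self.delays_ps.size

    def to_frame(self):
        import pandas as pd

        sigma = self.sigma if self.sigma is not None else np.full(len(self), np.nan)
        return pd.DataFrame(
            {
                "delay_ps": self.delays_ps,
                "yield": self.yields,
                "sigma": sigma,
                "channel": self.channel,
            }
        )


@dataclass
class ConvolvedPopulations:
    """Probe-convolved populations rho'_ii on the trace grid."""

    t_ps: np.ndarray
    populations: np.ndarray  # (n, 5)

    def population(self, i: int) -> np.ndarray:
        return self.populations[:, i - 1]

    def interpolate(self, delays_ps) -> np.ndarray:
        """All five rho'_ii at the requested delays, shape (len(delays), 5)."""
        delays = np.asarray(delays_ps, dtype=float)
        if delays.min() < self.t_ps[0] or delays.max() > self.t_ps[-1]:
            raise ExtrapolationError(
                f"delays [{delays.min():g}, {delays.max():g}] ps outside the "
                f"integrated range [{self.t_ps[0]:g}, {self.t_ps[-1]:g}] ps"
            )
        return np.stack(
            [np.interp(delays, self.t_ps, self.populations[:, i]) for i in range(5)],
            axis=1,
        )


def convolve_probe(
    trace: DensityMatrixTrace, probe_fwhm_fs: float = 70.0
) -> ConvolvedPopulations:
    """Convolve the populations with the probe intensity envelope.

    The kernel is an area-normalised Gaussian of the given FWHM, applied
    per uniform segment of the (possibly piecewise-uniform) grid with
    nearest-value edge handling, so constant asymptotic segments are
    left unchanged.  The segment covering the pulse region must resolve
    the kernel with at least 10 points per FWHM.
    """
    if not probe_fwhm_fs > 0:
        raise ParameterError("probe_fwhm_fs must be positive")
    sigma_ps = fwhm_to_sigma(probe_fwhm_fs) / FS_PER_PS
    fwhm_ps = probe_fwhm_fs / FS_PER_PS
    out = np.empty_like(trace.populations)
    for start, stop, step in trace.segments():
        block = trace.populations[start:stop]
        covers_pulse = trace.t_ps[start] < 1.0 and trace.t_ps[stop - 1] > -1.0
        if step <= 0:
            out[start:stop] = block
            continue
        if covers_pulse and fwhm_ps / step < 10.0:
            raise GridResolutionError(
                f"grid step {step * 1e3:g} fs too coarse for a "
                f"{probe_fwhm_fs:g} fs probe kernel (need >= 10 points/FWHM)"
            )
        out[start:stop] = gaussian_filter1d(
            block, sigma=sigma_ps / step, axis=0, mode="nearest", truncate=8.0
        )
    return ConvolvedPopulations(trace.t_ps, out)


def model_ion_yields(
    convolved: ConvolvedPopulations,
    coeffs: SignalCoefficients,
    osc: OscillationParams,
    delays: dict | np.ndarray,
) -> dict[str, IonYieldCurve]:
    """Evaluate the three model ion-yield channels at the given delays.

    ``delays`` is either one array shared by all channels or a mapping
    ``{channel: array}`` (the experimental scan designs differ between
    the water channel and the other two).  The parent channel sums
    states 2..4, the fragment channel 2..5, the water channel is
    ``C rho'_55`` with no oscillatory modulation.
    """
    if isinstance(delays, dict):
        delay_map = {ch: np.asarray(delays[ch], dtype=float) for ch in CHANNELS}
    else:
        d = np.asarray(delays, dtype=float)
        delay_map = {ch: d for ch in CHANNELS}

    out: dict[str, IonYieldCurve] = {}
    for ch in CHANNELS:
        d = delay_map[ch]
        rho = convolved.interpolate(d)  # (n, 5), columns rho'_11..rho'_55
        if ch == "parent":
            base = coeffs.A2 * rho[:, 1] + coeffs.A3 * rho[:, 2] + coeffs.A4 * rho[:, 3]
        elif ch == "fragment":
            base = (
                coeffs.B2 * rho[:, 1]
                + coeffs.B3 * rho[:, 2]
                + coeffs.B4 * rho[:, 3]
                + coeffs.B5 * rho[:, 4]
            )
        else:
            base = coeffs.C * rho[:, 4]
        out[ch] = IonYieldCurve(d, base * osc.modulation(d, ch), channel=ch)
    return out
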