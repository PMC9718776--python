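"""Seeded synthetic datasets with the statistical structure the analysis assumes.

Every generator is a pure function of (ground truth, design, seed): the
same inputs give bit-identical output.  The defaults reproduce the
experimental study conditions this package targets:

* delay designs: 417 fs steps for -1.535 ... 6.805 ps, one 834 fs step,
  1.668 ps steps beyond 7.639 ps for the parent/fragment channels;
  -5.705 ... 140.245 ps in 4.17 ps steps for the water channel;
* ion-yield truth: the best-fit five-level time constants
  (tau2 = 445 fs, tau3 = 13 ps, tau4 = 96 ps), Rabi frequency
  3.4 rad/ps, IRF 381 fs, the frozen oscillation parameters, and 3%
  Gaussian noise relative to each channel's peak model value;
* kinetic-energy spectra: a delay-independent background (standing in
  for the water-dimer contribution) plus, after the dissociation onset,
  a Maxwell-Boltzmann component whose analytic mean follows the
  ion-dipole model (R_eq = 490 pm, v = 12 m/s, t_d = 51 ps,
  theta = 38 deg, E_a = 4.57 eV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ParameterError
from .kinetics import ExcitationPulse, LevelScheme, integrate_bloch
from .signal import (
    CHANNELS,
    IonYieldCurve,
    OscillationParams,
    SignalCoefficients,
    convolve_probe,
    model_ion_yields,
)
from .tker import (
    _MB_MEAN_FACTOR,
    IonDipoleModel,
    KESpectrum,
    tker_evolution,
)

__all__ = [
    "ScanDesign",
    "GroundTruth",
    "default_ground_truth",
    "generate_ion_yield_scan",
    "generate_ke_spectra",
    "generate_mean_tker_curve",
]


@dataclass(frozen=True)
class ScanDesign:
    """Piecewise-uniform pump-probe delay grid plus a noise model.

    ``segments`` are non-overlapping, increasing (start, stop, step)
    triples in ps (stop inclusive up to rounding).  ``noise`` is
    "gaussian" (sigma = ``noise_frac`` of the channel's peak model
    value) or "poisson" (counting statistics at ``shots_per_point``
    shots and ``counts_per_shot_at_peak`` expected peak counts).
    """

    segments: tuple[tuple[float, float, float], ...]
    shots_per_point: int = 8000
    noise: str = "gaussian"
    noise_frac: float = 0.03
    counts_per_shot_at_peak: float = 0.05

    def __post_init__(self) -> None:
        prev_stop = -math.inf
        for start, stop, step in self.segments:
            if not (stop > start and step > 0):
                raise ParameterError("each segment needs stop > start, step > 0")
            if start <= prev_stop:
                raise ParameterError("segments must be increasing, non-overlapping")
            prev_stop = stop
        if self.noise not in ("gaussian", "poisson"):
            raise ParameterError("noise must be 'gaussian' or 'poisson'")

    def delays(self) -> np.ndarray:
        parts = []
        for start, stop, step in self.segments:
            n = int(math.floor((stop - start) / step + 1e-9))
            parts.append(start + step * np.arange(n + 1))
        return np.concatenate(parts)

    @classmethod
    def indole_channels(cls, t_max_ps: float = 120.0, **kw) -> "ScanDesign":
        """The parent/fragment scan: 417 fs steps to 6.805 ps, one
        834 fs step to 7.639 ps, then 1.668 ps steps."""
        return cls(
            segments=(
                (-1.535, 6.805, 0.417),
                (7.639, t_max_ps, 1.668),
            ),
            shots_per_point=8000,
            **kw,
        )

    @classmethod
    def water_channel(cls, **kw) -> "ScanDesign":
        """The water-ion scan: -5.705 ... 140.245 ps in 4.17 ps steps."""
        return cls(
            segments=((-5.705, 140.245, 4.17),),
            shots_per_point=41000,
            **kw,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Complete generating parameter set of a synthetic dataset."""

    scheme: LevelScheme = field(default_factory=LevelScheme)
    pulse: ExcitationPulse = field(default_factory=ExcitationPulse)
    coeffs: SignalCoefficients = field(default_factory=SignalCoefficients)
    osc: OscillationParams = field(default_factory=OscillationParams)
    ion_dipole: IonDipoleModel = field(default_factory=IonDipoleModel)
    probe_fwhm_fs: float = 70.0
    baselines: tuple[float, float, float] = (0.10, 0.10, 0.05)
    kT_bg_mev: float = 60.0
    bg_amplitude: float = 1.0
    dyn_amplitude: float = 1.0
    mb_form: str = "3d"

    def baseline(self, channel: str) -> float:
        return dict(zip(CHANNELS, self.baselines))[channel]

    def to_dict(self) -> dict:
        return {
            "scheme": asdict(self.scheme),
            "pulse": asdict(self.pulse),
            "coeffs": asdict(self.coeffs),
            "osc": asdict(self.osc),
            "ion_dipole": asdict(self.ion_dipole),
            "probe_fwhm_fs": self.probe_fwhm_fs,
            "baselines": list(self.baselines),
            "kT_bg_mev": self.kT_bg_mev,
            "bg_amplitude": self.bg_amplitude,
            "dyn_amplitude": self.dyn_amplitude,
            "mb_form": self.mb_form,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            scheme=LevelScheme(**d["scheme"]),
            pulse=ExcitationPulse(**d["pulse"]),
            coeffs=SignalCoefficients(**d["coeffs"]),
            osc=OscillationParams(**d["osc"]),
            ion_dipole=IonDipoleModel(**d["ion_dipole"]),
            probe_fwhm_fs=d["probe_fwhm_fs"],
            baselines=tuple(d["baselines"]),
            kT_bg_mev=d["kT_bg_mev"],
            bg_amplitude=d["bg_amplitude"],
            dyn_amplitude=d["dyn_amplitude"],
            mb_form=d["mb_form"],
        )


def default_ground_truth() -> GroundTruth:
    """The study-condition defaults (all dataclass defaults)."""
    return GroundTruth()


def _noiseless_curves(
    truth: GroundTruth, delay_map: dict[str, np.ndarray]
) -> dict[str, IonYieldCurve]:
    all_d = np.concatenate(list(delay_map.values()))
    t_start = min(-5.0, all_d.min() - 0.5)
    t_end = all_d.max() + 1.0
    trace = integrate_bloch(truth.scheme, truth.pulse, t_start, t_end, method="hybrid")
    conv = convolve_probe(trace, truth.probe_fwhm_fs)
    return model_ion_yields(conv, truth.coeffs, truth.osc, delay_map)


def generate_ion_yield_scan(
    truth: GroundTruth,
    design: ScanDesign | dict[str, ScanDesign] | None = None,
    seed: int = 0,
) -> dict[str, IonYieldCurve]:
    """Synthetic three-channel delay scan.

    Evaluates the forward model on the design grid, adds each channel's
    constant baseline, then applies the design's noise model and
    attaches the matching per-point 1-sigma errors.  Deterministic under
    (truth, design, seed).
    """
    if design is None:
        design = {
            "parent": ScanDesign.indole_channels(),
            "fragment": ScanDesign.indole_channels(),
            "water": ScanDesign.water_channel(),
        }
    if isinstance(design, ScanDesign):
        design = {ch: design for ch in CHANNELS}
    delay_map = {ch: design[ch].delays() for ch in CHANNELS}
    model = _noiseless_curves(truth, delay_map)
    rng = np.random.default_rng(seed)
    out: dict[str, IonYieldCurve] = {}
    for ch in CHANNELS:
        des = design[ch]
        clean = model[ch].yields + truth.baseline(ch)
        peak = float(np.max(model[ch].yields))
        if des.noise == "gaussian":
            sig = des.noise_frac * peak
            if sig > 0:
                y = clean + rng.normal(0.0, sig, size=clean.size)
            else:
                y = clean.copy()
            sigma = np.full(clean.size, max(sig, 1e-12))
        else:  # poisson counting statistics
            scale = des.shots_per_point * des.counts_per_shot_at_peak / max(peak, 1e-12)
            counts = rng.poisson(np.clip(clean * scale, 0, None))
            y = counts / scale
            sigma = np.sqrt(np.clip(counts, 1, None)) / scale
        out[ch] = IonYieldCurve(delay_map[ch], y, sigma, channel=ch)
    return out


def _kT_dyn_mev(truth: GroundTruth, t_ps: float) -> float:
    """kT of the dynamic component so that its analytic mean follows
    the ion-dipole TKER evolution."""
    mean_ev = float(tker_evolution(truth.ion_dipole, t_ps))
    return mean_ev * 1e3 / _MB_MEAN_FACTOR[truth.mb_form]


def _mb_samples(rng: np.random.Generator, kT_mev: float, n: int, form: str) -> np.ndarray:
    if form == "3d":
        return rng.gamma(1.5, kT_mev, size=n)
    return rng.exponential(kT_mev, size=n)


def generate_ke_spectra(
    truth: GroundTruth,
    delays_ps,
    samples_per_delay: int = 20000,
    bin_edges_mev: np.ndarray | None = None,
    seed: int = 0,
) -> list[KESpectrum]:
    """Synthetic delay-resolved TKER spectra.

    Each spectrum is a histogram of draws from the static background
    distribution (Maxwell-Boltzmann at ``kT_bg_mev``, delay-independent)
    plus, for delays past the dissociation onset, draws from a
    Maxwell-Boltzmann component whose analytic mean equals the
    ion-dipole prediction at that delay.  The relative strength of the
    two components is ``dyn_amplitude : bg_amplitude``.
    """
    delays = np.atleast_1d(np.asarray(delays_ps, dtype=float))
    if bin_edges_mev is None:
        bin_edges_mev = np.arange(0.0, 605.0, 10.0)
    if not np.any(delays < 0):
        import warnings

        warnings.warn(
            "no negative delays: background subtraction cannot be tested",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    spectra = []
    for t in delays:
        dynamic = t > truth.ion_dipole.t_d_ps
        # background statistics are delay-independent; the dynamic
        # component rides on top after the dissociation onset
        n_bg = samples_per_delay
        n_dyn = (
            int(round(samples_per_delay * truth.dyn_amplitude / truth.bg_amplitude))
            if dynamic
            else 0
        )
        draws = [_mb_samples(rng, truth.kT_bg_mev, n_bg, truth.mb_form)]
        if n_dyn > 0:
            draws.append(_mb_samples(rng, _kT_dyn_mev(truth, t), n_dyn, truth.mb_form))
        counts, _ = np.histogram(np.concatenate(draws), bins=bin_edges_mev)
        spectra.append(
            KESpectrum(bin_edges_mev.copy(), counts.astype(float), delay_ps=float(t))
        )
    return spectra


def generate_mean_tker_curve(
    truth: GroundTruth,
    delays_ps=None,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic mean-TKER-versus-delay series (meV).

    Evaluates the ion-dipole model on the delay grid (default: 55 to
    140 ps in 1.668 ps steps, the design of the high-statistics scan
    used for the release-evolution analysis) and applies multiplicative
    Gaussian noise of relative size ``noise_frac``.
    Returns (delays_ps, mean_tker_mev, sigma_mev).
    """
    if delays_ps is None:
        delays_ps = np.arange(55.0, 140.0 + 1e-9, 1.668)
    delays = np.asarray(delays_ps, dtype=float)
    clean_mev = tker_evolution(truth.ion_dipole, delays) * 1e3
    rng = np.random.default_rng(seed)
    sigma = noise_frac * clean_mev
    noisy = clean_mev + rng.normal(0.0, 1.0, size=clean_mev.size) * sigma
    return delays, noisy, sigma
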