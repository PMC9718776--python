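"""Global fit of the five-level reaction model to three ion-yield channels.

:class:`ReactionKineticsModel` follows the Model/Results idiom: it is
built from the three measured :class:`~microsolv.signal.IonYieldCurve`
objects and fixed experimental inputs (pump pulse, probe FWHM, frozen
oscillation parameters), and :meth:`ReactionKineticsModel.fit` runs a
weighted Levenberg-Marquardt optimisation of the shared time constants
(tau2, tau3, tau4) and the per-channel linear coefficients, re-solving
the density-matrix equations at every iteration.  The returned
:class:`ReactionKineticsResults` carries estimates, 1-sigma errors from
the chi^2-scaled covariance, reduced chi^2, R^2 (joint and per channel)
and a text :meth:`~ReactionKineticsResults.summary`.

Time constants are fitted in log10 space to enforce positivity across
three decades of timescales; coefficients are bounded at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import curve_fit

from .exceptions import AliasingError, FitError, ParameterError
from .kinetics import ExcitationPulse, LevelScheme, integrate_bloch
from .signal import (
    CHANNELS,
    IonYieldCurve,
    OscillationParams,
    SignalCoefficients,
    convolve_probe,
    model_ion_yields,
)

__all__ = [
    "ReactionKineticsModel",
    "ReactionKineticsResults",
    "OscillationFit",
    "fit_reaction_model",
    "fit_oscillation",
]

_COEF_NAMES = ("A2", "A3", "A4", "B2", "B3", "B4", "B5", "C")


@dataclass
class ReactionKineticsResults:
    """Estimates and diagnostics of the global five-level fit."""

    tau2_fs: float
    tau3_ps: float
    tau4_ps: float
    tau2_stderr_fs: float
    tau3_stderr_ps: float
    tau4_stderr_ps: float
    coefficients: SignalCoefficients
    coefficient_stderr: dict[str, float]
    redchi: float
    rsquared: float
    rsquared_by_channel: dict[str, float]
    nfree: int
    ndata: int
    nfev: int
    success: bool
    message: str
    baselines: dict[str, float]
    covar: np.ndarray | None
    model: "ReactionKineticsModel" = field(repr=False)

    @property
    def scheme(self) -> LevelScheme:
        """Fitted level scheme (for re-simulation)."""
        return LevelScheme(self.tau2_fs, self.tau3_ps, self.tau4_ps)

    def predict(self, delays=None) -> dict[str, IonYieldCurve]:
        """Model curves at the fitted parameters (baseline-free)."""
        if delays is None:
            delays = {ch: c.delays_ps for ch, c in self.model.curves.items()}
        return self.model.simulate(self.scheme, self.coefficients, delays)

    def to_dict(self) -> dict:
        """Flat key-value report suitable for YAML/JSON serialization."""
        out = {
            "tau2_fs": float(self.tau2_fs),
            "tau2_stderr_fs": float(self.tau2_stderr_fs),
            "tau3_ps": float(self.tau3_ps),
            "tau3_stderr_ps": float(self.tau3_stderr_ps),
            "tau4_ps": float(self.tau4_ps),
            "tau4_stderr_ps": float(self.tau4_stderr_ps),
            "redchi": float(self.redchi),
            "rsquared": float(self.rsquared),
            "nfree": int(self.nfree),
            "ndata": int(self.ndata),
            "nfev": int(self.nfev),
            "success": bool(self.success),
        }
        for name in _COEF_NAMES:
            out[name] = float(getattr(self.coefficients, name))
            out[f"{name}_stderr"] = float(self.coefficient_stderr.get(name, math.nan))
        for ch in CHANNELS:
            out[f"rsquared_{ch}"] = float(self.rsquared_by_channel[ch])
            out[f"baseline_{ch}"] = float(self.baselines[ch])
        return out

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            "Five-level reaction-model fit",
            "=" * 46,
            f"channels: {', '.join(CHANNELS)}   n = {self.ndata}, "
            f"dof = {self.nfree}",
            f"reduced chi^2 = {self.redchi:.3f}   R^2 (joint) = {self.rsquared:.4f}",
            "-" * 46,
            f"tau2 = {self.tau2_fs:9.1f} +/- {self.tau2_stderr_fs:.1f} fs",
            f"tau3 = {self.tau3_ps:9.2f} +/- {self.tau3_stderr_ps:.2f} ps",
            f"tau4 = {self.tau4_ps:9.2f} +/- {self.tau4_stderr_ps:.2f} ps",
            "-" * 46,
        ]
        for name in _COEF_NAMES:
            err = self.coefficient_stderr.get(name, math.nan)
            lines.append(
                f"{name:>3s} = {getattr(self.coefficients, name):9.4f} +/- {err:.4f}"
            )
        lines.append("-" * 46)
        for ch in CHANNELS:
            lines.append(
                f"R^2 ({ch}) = {self.rsquared_by_channel[ch]:.4f}   "
                f"baseline = {self.baselines[ch]:.4g}"
            )
        return "\n".join(lines)


class ReactionKineticsModel:
    """Joint model of three background-corrected ion-yield channels.

    Parameters
    ----------
    curves : mapping channel -> IonYieldCurve
        Measured delay scans for "parent", "fragment" and "water".
    pulse : ExcitationPulse
        Fixed pump parameters (Rabi frequency, IRF width).
    osc : OscillationParams
        Oscillation parameters, frozen during the fit (calibrated once
        on a high-resolution scan, see :func:`fit_oscillation`).
    probe_fwhm_fs : float
        FWHM of the probe intensity envelope used to convolve the
        populations.
    baseline : {"negative-delay", "none"}
        "negative-delay" (default) subtracts, per channel, the mean
        signal at delays < ``baseline_before_ps`` before fitting.
    """

    def __init__(
        self,
        curves: dict[str, IonYieldCurve],
        pulse: ExcitationPulse | None = None,
        osc: OscillationParams | None = None,
        probe_fwhm_fs: float = 70.0,
        baseline: str = "negative-delay",
        baseline_before_ps: float = -0.5,
    ) -> None:
        missing = [ch for ch in CHANNELS if ch not in curves]
        if missing:
            raise ParameterError(f"missing channels: {missing}")
        self.curves = {ch: curves[ch] for ch in CHANNELS}
        for ch, c in self.curves.items():
            if c.sigma is None:
                raise ParameterError(f"channel {ch!r} has no 1-sigma errors")
            if np.any(c.sigma <= 0):
                raise ParameterError(f"channel {ch!r} has non-positive sigma")
        self.pulse = pulse if pulse is not None else ExcitationPulse()
        self.osc = osc if osc is not None else OscillationParams()
        self.probe_fwhm_fs = probe_fwhm_fs
        if baseline not in ("negative-delay", "none"):
            raise ParameterError("baseline must be 'negative-delay' or 'none'")
        self.baseline_mode = baseline
        self.baseline_before_ps = baseline_before_ps
        self.baselines = self._estimate_baselines()
        all_delays = np.concatenate([c.delays_ps for c in self.curves.values()])
        self._t_start = min(-5.0, all_delays.min() - 0.5)
        self._t_end = all_delays.max() + 1.0

    def _estimate_baselines(self) -> dict[str, float]:
        if self.baseline_mode == "none":
            return {ch: 0.0 for ch in CHANNELS}
        out = {}
        for ch, c in self.curves.items():
            mask = c.delays_ps < self.baseline_before_ps
            out[ch] = float(c.yields[mask].mean()) if mask.any() else 0.0
        return out

    def corrected_yields(self, channel: str) -> np.ndarray:
        """Yields with the per-channel negative-delay baseline removed."""
        return self.curves[channel].yields - self.baselines[channel]

    def _apply_baseline_operator(self, channel: str, model_yields: np.ndarray) -> np.ndarray:
        """Apply the same baseline estimator to the model as to the data.

        The data baseline (mean at delays < cutoff) also absorbs any
        small model signal at those delays; subtracting the model's own
        negative-delay mean keeps the comparison unbiased.
        """
        if self.baseline_mode == "none":
            return model_yields
        mask = self.curves[channel].delays_ps < self.baseline_before_ps
        if not mask.any():
            return model_yields
        return model_yields - float(model_yields[mask].mean())

    def simulate(
        self,
        scheme: LevelScheme,
        coeffs: SignalCoefficients,
        delays: dict | np.ndarray | None = None,
    ) -> dict[str, IonYieldCurve]:
        """Forward model: integrate, convolve, combine, modulate."""
        if delays is None:
            delays = {ch: c.delays_ps for ch, c in self.curves.items()}
        trace = integrate_bloch(
            scheme, self.pulse, self._t_start, self._t_end, method="hybrid"
        )
        conv = convolve_probe(trace, self.probe_fwhm_fs)
        return model_ion_yields(conv, coeffs, self.osc, delays)

    # -- fitting ---------------------------------------------------------

    def _make_params(self, start: LevelScheme, coeffs0: SignalCoefficients):
        params = lmfit.Parameters()
        params.add("log_tau2_fs", value=math.log10(start.tau2_fs), min=0.5, max=4.5)
        params.add("log_tau3_ps", value=math.log10(start.tau3_ps), min=-2.0, max=3.0)
        params.add("log_tau4_ps", value=math.log10(start.tau4_ps), min=-1.0, max=4.0)
        for name in _COEF_NAMES:
            params.add(name, value=getattr(coeffs0, name), min=0.0)
        return params

    @staticmethod
    def _unpack(params) -> tuple[LevelScheme, SignalCoefficients]:
        scheme = LevelScheme(
            10.0 ** params["log_tau2_fs"].value,
            10.0 ** params["log_tau3_ps"].value,
            10.0 ** params["log_tau4_ps"].value,
        )
        coeffs = SignalCoefficients(
            **{name: params[name].value for name in _COEF_NAMES}
        )
        return scheme, coeffs

    def _residuals(self, params) -> np.ndarray:
        scheme, coeffs = self._unpack(params)
        model = self.simulate(scheme, coeffs)
        res = []
        for ch in CHANNELS:
            data = self.corrected_yields(ch)
            mod = self._apply_baseline_operator(ch, model[ch].yields)
            res.append((data - mod) / self.curves[ch].sigma)
        return np.concatenate(res)

    def _default_start_coeffs(self) -> SignalCoefficients:
        peaks = {
            ch: max(float(np.max(self.corrected_yields(ch))), 1e-12)
            for ch in CHANNELS
        }
        return SignalCoefficients(
            A2=peaks["parent"],
            A3=0.5 * peaks["parent"],
            A4=0.25 * peaks["parent"],
            B2=0.25 * peaks["fragment"],
            B3=0.5 * peaks["fragment"],
            B4=0.5 * peaks["fragment"],
            B5=peaks["fragment"],
            C=peaks["water"],
        )

    def fit(
        self,
        start: LevelScheme | None = None,
        start_coeffs: SignalCoefficients | None = None,
        max_nfev: int | None = None,
    ) -> ReactionKineticsResults:
        """Run the global weighted Levenberg-Marquardt fit."""
        if start is None:
            start = LevelScheme(600.0, 8.0, 70.0)
        if start_coeffs is None:
            start_coeffs = self._default_start_coeffs()
        params = self._make_params(start, start_coeffs)
        minres = lmfit.minimize(
            self._residuals,
            params,
            method="leastsq",
            max_nfev=max_nfev,
            xtol=1e-9,
            ftol=1e-9,
        )
        scheme, coeffs = self._unpack(minres.params)

        def _log_err(pname: str, value: float) -> float:
            p = minres.params[pname]
            if p.stderr is None:
                return math.nan
            return value * math.log(10.0) * p.stderr

        coef_err = {}
        for name in _COEF_NAMES:
            se = minres.params[name].stderr
            coef_err[name] = float(se) if se is not None else math.nan

        model = self.simulate(scheme, coeffs)
        ss_res_tot = 0.0
        ss_tot_tot = 0.0
        r2 = {}
        for ch in CHANNELS:
            data = self.corrected_yields(ch)
            resid = data - self._apply_baseline_operator(ch, model[ch].yields)
            ss_res = float(np.sum(resid**2))
            ss_tot = float(np.sum((data - data.mean()) ** 2))
            r2[ch] = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
            ss_res_tot += ss_res
            ss_tot_tot += ss_tot

        if minres.nfree <= 0:
            raise FitError("no degrees of freedom left in the global fit")

        return ReactionKineticsResults(
            tau2_fs=scheme.tau2_fs,
            tau3_ps=scheme.tau3_ps,
            tau4_ps=scheme.tau4_ps,
            tau2_stderr_fs=_log_err("log_tau2_fs", scheme.tau2_fs),
            tau3_stderr_ps=_log_err("log_tau3_ps", scheme.tau3_ps),
            tau4_stderr_ps=_log_err("log_tau4_ps", scheme.tau4_ps),
            coefficients=coeffs,
            coefficient_stderr=coef_err,
            redchi=float(minres.redchi),
            rsquared=1.0 - ss_res_tot / ss_tot_tot,
            rsquared_by_channel=r2,
            nfree=int(minres.nfree),
            ndata=int(minres.ndata),
            nfev=int(minres.nfev),
            success=bool(minres.success),
            message=str(minres.message),
            baselines=dict(self.baselines),
            covar=getattr(minres, "covar", None),
            model=self,
        )


def fit_reaction_model(
    curves: dict[str, IonYieldCurve],
    scheme_init: LevelScheme | None = None,
    pulse: ExcitationPulse | None = None,
    osc_fixed: OscillationParams | None = None,
    probe_fwhm_fs: float = 70.0,
    **fit_kwargs,
) -> ReactionKineticsResults:
    """Convenience wrapper: build a :class:`ReactionKineticsModel` and fit."""
    model = ReactionKineticsModel(
        curves, pulse=pulse, osc=osc_fixed, probe_fwhm_fs=probe_fwhm_fs
    )
    return model.fit(start=scheme_init, **fit_kwargs)


# -- oscillation calibration ---------------------------------------------


@dataclass(frozen=True)
class OscillationFit:
    """Result of the one-off oscillation calibration."""

    a: float
    b: float
    omega_rad_per_ps: float
    phi: float
    a_stderr: float
    b_stderr: float
    omega_stderr: float
    phi_stderr: float
    redchi: float

    @property
    def period_ps(self) -> float:
        return 2.0 * math.pi / self.omega_rad_per_ps


def _dominant_angular_freq(t: np.ndarray, y: np.ndarray) -> float:
    """Periodogram estimate of the strongest non-DC angular frequency."""
    step = np.median(np.diff(t))
    grid = np.arange(t[0], t[-1] + step / 2, step)
    yu = np.interp(grid, t, y)
    yu = yu - yu.mean()
    spec = np.abs(np.fft.rfft(yu * np.hanning(yu.size)))
    freqs = np.fft.rfftfreq(yu.size, d=step)
    k = int(np.argmax(spec[1:])) + 1
    return 2.0 * math.pi * freqs[k]


def fit_oscillation(
    curve: IonYieldCurve,
    envelope=None,
    omega_init: float | None = None,
) -> OscillationFit:
    """Calibrate (a, b, omega, phi) from a high-resolution delay scan.

    The signal is modelled as ``env(t) * (a + b cos(omega t + phi))``
    with a fixed, slowly varying envelope ``env`` (a callable; constant 1
    by default).  The frequency is seeded from the periodogram unless
    ``omega_init`` is given.  The curve must span at least three periods
    sampled with at least four points per period, otherwise an
    :class:`~microsolv.exceptions.AliasingError` is raised.
    """
    t, y = curve.delays_ps, curve.yields
    if envelope is None:
        env = np.ones_like(t)
    else:
        env = np.asarray(envelope(t), dtype=float)
    if np.any(env <= 0):
        raise ParameterError("envelope must be strictly positive on the scan")

    omega0 = omega_init if omega_init is not None else _dominant_angular_freq(t, y / env)
    if omega0 <= 0:
        raise FitError("could not seed the oscillation frequency")
    period = 2.0 * math.pi / omega0
    span = t[-1] - t[0]
    max_step = np.max(np.diff(t))
    if span < 3.0 * period:
        raise AliasingError(
            f"scan spans {span / period:.1f} periods; need at least 3"
        )
    if period / max_step < 4.0:
        raise AliasingError(
            f"sampling {period / max_step:.1f} points/period; need at least 4"
        )

    ratio = y / env
    a0 = float(ratio.mean())
    b0 = max(float(ratio.std()) * math.sqrt(2.0), 1e-12)

    def model(tt, a, b, w, p):
        return np.interp(tt, t, env) * (a + b * np.cos(w * tt + p))

    sigma = curve.sigma if curve.sigma is not None else None
    best = None
    # phase is the one parameter with serious local minima; multi-start it
    for phi0 in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2):
        try:
            popt, pcov = curve_fit(
                model,
                t,
                y,
                p0=[a0, b0, omega0, phi0],
                sigma=sigma,
                absolute_sigma=sigma is not None,
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = y - model(t, *popt)
        cost = float(np.sum(resid**2))
        if best is None or cost < best[2]:
            best = (popt, pcov, cost)
    if best is None:
        raise FitError("oscillation fit did not converge")
    popt, pcov, cost = best
    a, b, w, p = popt
    if b < 0:  # normalise sign/phase convention
        b = -b
        p += math.pi
    p = p % (2.0 * math.pi)
    err = np.sqrt(np.diag(pcov))
    dof = max(t.size - 4, 1)
    return OscillationFit(
        a=float(a),
        b=float(b),
        omega_rad_per_ps=float(w),
        phi=float(p),
        a_stderr=float(err[0]),
        b_stderr=float(err[1]),
        omega_stderr=float(err[2]),
        phi_stderr=float(err[3]),
        redchi=cost / dof,
    )
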