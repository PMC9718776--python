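"""Total kinetic energy release (TKER) analysis of the water-ion channel.

Covers the full chain from projected fragment kinetic energies to the
classical ion-dipole picture of the slow fragment separation:

* momentum-conservation transform of one fragment's kinetic energy to
  the total release, ``TKER = E_K * m_parent / (m_parent - m_fragment)``;
* subtraction of the delay-independent background (mean of the
  negative-delay spectra, where only the water-dimer contribution is
  present);
* Maxwell-Boltzmann fits of the background-subtracted distributions,
  whose analytic means trace the delay evolution of the release;
* the ion-dipole model: a point charge leaving a fixed permanent dipole
  along ``R(t) = R_eq + v (t - t_d)`` feels
  ``V = q mu cos(theta) / (4 pi eps0 R^2)``, so
  ``TKER(t) = E_pump - E_a + V(t)`` decays monotonically to the
  asymptote ``E_pump - E_a``.

Energies are handled in eV internally and reported in meV for spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .constants import DEBYE, E_CHARGE, EPSILON_0, M_CLUSTER_U, M_WATER_U
from .exceptions import (
    BinningError,
    FitError,
    InsufficientSignalError,
    ParameterError,
    PreconditionError,
)

__all__ = [
    "KESpectrum",
    "MaxwellBoltzmannFit",
    "IonDipoleModel",
    "IonDipoleResults",
    "IonDipoleTKERModel",
    "ke_to_tker",
    "subtract_negative_delay_background",
    "fit_maxwell_boltzmann",
    "ion_dipole_potential",
    "tker_evolution",
    "fit_ion_dipole",
]


def ke_to_tker(fragment_ke, m_fragment_u: float = M_WATER_U,
               m_parent_u: float = M_CLUSTER_U):
    """Total kinetic energy release from one fragment's kinetic energy.

    Momentum conservation in a two-body dissociation gives
    ``TKER = E_K * m_parent / (m_parent - m_fragment)`` (the co-fragment
    carries the rest).  Linear and strictly increasing in ``E_K``; any
    energy unit is preserved.
    """
    if not (m_fragment_u > 0 and m_parent_u > 0):
        raise ParameterError("masses must be positive")
    if m_parent_u <= m_fragment_u:
        raise ParameterError("parent mass must exceed fragment mass")
    return np.asarray(fragment_ke, dtype=float) * m_parent_u / (m_parent_u - m_fragment_u)


@dataclass
class KESpectrum:
    """Binned (projected) kinetic-energy or TKER distribution at one delay.

    ``delay_ps = None`` labels a delay-averaged spectrum such as the
    negative-delay background.  Counts may go negative after background
    subtraction.
    """

    bin_edges_mev: np.ndarray
    counts: np.ndarray
    delay_ps: float | None = None
    m_fragment_u: float = M_WATER_U
    m_parent_u: float = M_CLUSTER_U
    is_tker: bool = True

    def __post_init__(self) -> None:
        self.bin_edges_mev = np.asarray(self.bin_edges_mev, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges_mev.size - 1:
            raise ParameterError("need len(counts) == len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges_mev) <= 0) or self.bin_edges_mev[0] < 0:
            raise ParameterError("bin edges must be non-negative and increasing")
        if not np.all(np.isfinite(self.counts)):
            raise ParameterError("counts must be finite")

    @property
    def centers_mev(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_mev[:-1] + self.bin_edges_mev[1:])

    @property
    def widths_mev(self) -> np.ndarray:
        return np.diff(self.bin_edges_mev)

    def to_tker(self) -> "KESpectrum":
        """Rescale the energy axis from fragment KE to total release."""
        if self.is_tker:
            return self
        edges = ke_to_tker(self.bin_edges_mev, self.m_fragment_u, self.m_parent_u)
        return replace(self, bin_edges_mev=edges, is_tker=True)

    def same_binning(self, other: "KESpectrum") -> bool:
        return (
            self.bin_edges_mev.size == other.bin_edges_mev.size
            and np.allclose(self.bin_edges_mev, other.bin_edges_mev, rtol=1e-9)
        )


def subtract_negative_delay_background(
    spectra: list[KESpectrum],
) -> tuple[list[KESpectrum], KESpectrum]:
    """Remove the delay-independent component estimated at negative delays.

    The background is the per-bin mean of all spectra with
    ``delay_ps < 0``; it is subtracted from every spectrum (so the
    negative-delay spectra become zero-mean noise) and returned alongside.
    """
    if not spectra:
        raise PreconditionError("no spectra given")
    ref = spectra[0]
    for s in spectra[1:]:
        if not ref.same_binning(s):
            raise BinningError("spectra have mismatched energy binning")
    neg = [s for s in spectra if s.delay_ps is not None and s.delay_ps < 0]
    if not neg:
        raise PreconditionError("need at least one negative-delay spectrum")
    bg_counts = np.mean([s.counts for s in neg], axis=0)
    background = KESpectrum(
        ref.bin_edges_mev.copy(),
        bg_counts,
        delay_ps=None,
        m_fragment_u=ref.m_fragment_u,
        m_parent_u=ref.m_parent_u,
        is_tker=ref.is_tker,
    )
    subtracted = [replace(s, counts=s.counts - bg_counts) for s in spectra]
    return subtracted, background


# -- Maxwell-Boltzmann fitting -------------------------------------------

#: analytic mean of each supported functional form, in units of kT
_MB_MEAN_FACTOR = {"3d": 1.5, "projected": 1.0}


def mb_shape(energy, kT: float, form: str = "3d"):
    """Unnormalised Maxwell-Boltzmann energy distribution.

    ``"3d"``: P(E) ~ sqrt(E) exp(-E/kT), the speed distribution in
    energy form (mean 3kT/2).  ``"projected"``: P(E) ~ exp(-E/kT)
    (mean kT), appropriate for a 2D-projected distribution.
    """
    e = np.asarray(energy, dtype=float)
    if form == "3d":
        return np.sqrt(np.clip(e, 0, None)) * np.exp(-e / kT)
    if form == "projected":
        return np.exp(-e / kT)
    raise ParameterError(f"unknown Maxwell-Boltzmann form {form!r}")


@dataclass(frozen=True)
class MaxwellBoltzmannFit:
    """Fitted characteristic energy and derived analytic mean (meV)."""

    kT_mev: float
    amplitude: float
    form: str
    kT_stderr_mev: float
    redchi: float

    @property
    def mean_mev(self) -> float:
        """Analytic mean of the fitted form: 3kT/2 (3d) or kT (projected)."""
        return _MB_MEAN_FACTOR[self.form] * self.kT_mev

    @property
    def mean_stderr_mev(self) -> float:
        return _MB_MEAN_FACTOR[self.form] * self.kT_stderr_mev


def fit_maxwell_boltzmann(
    spectrum: KESpectrum,
    form: str = "3d",
    sigma: np.ndarray | None = None,
) -> MaxwellBoltzmannFit:
    """Weighted least-squares Maxwell-Boltzmann fit of one spectrum.

    The spectrum should be background-subtracted; the fit refuses
    spectra whose total signal is not positive.  The reported mean is
    the analytic mean of the fitted form, not the histogram mean.
    """
    if form not in _MB_MEAN_FACTOR:
        raise ParameterError(f"unknown Maxwell-Boltzmann form {form!r}")
    e = spectrum.centers_mev
    y = spectrum.counts
    total = float(np.sum(y * spectrum.widths_mev))
    if total <= 0:
        raise InsufficientSignalError("total signal is not positive")
    # moment-based seed for kT
    pos = np.clip(y, 0, None)
    mean0 = float(np.sum(e * pos) / np.sum(pos))
    kT0 = max(mean0 / _MB_MEAN_FACTOR[form], 1e-3)
    amp0 = float(np.max(pos)) / max(float(np.max(mb_shape(e, kT0, form))), 1e-300)

    def model(ee, amp, kT):
        return amp * mb_shape(ee, kT, form)

    try:
        popt, pcov = curve_fit(
            model,
            e,
            y,
            p0=[amp0, kT0],
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Maxwell-Boltzmann fit failed: {exc}") from exc
    resid = y - model(e, *popt)
    dof = max(e.size - 2, 1)
    if sigma is not None:
        redchi = float(np.sum((resid / sigma) ** 2) / dof)
    else:
        redchi = float(np.sum(resid**2) / dof)
    return MaxwellBoltzmannFit(
        kT_mev=float(popt[1]),
        amplitude=float(popt[0]),
        form=form,
        kT_stderr_mev=float(np.sqrt(pcov[1, 1])),
        redchi=redchi,
    )


# -- ion-dipole model ----------------------------------------------------


def ion_dipole_potential(
    r_pm, theta_deg: float = 38.0, mu_debye: float = 1.96, q_e: float = 1.0
):
    """Charge-dipole interaction energy in eV.

    ``V = q mu cos(theta) / (4 pi eps0 R^2)`` for a point charge ``q``
    (elementary charges) at distance ``R`` (pm) from a permanent dipole
    ``mu`` (debye) at fixed angle ``theta``; higher-order terms
    (ion-induced dipole, dipole-dipole) are neglected.
    """
    r = np.asarray(r_pm, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("separation R must be positive")
    r_m = r * 1e-12
    v_joule = (
        q_e
        * E_CHARGE
        * mu_debye
        * DEBYE
        * math.cos(math.radians(theta_deg))
        / (4.0 * math.pi * EPSILON_0 * r_m**2)
    )
    return v_joule / E_CHARGE  # eV


@dataclass(frozen=True)
class IonDipoleModel:
    """Parameters of the classical ion-dipole separation model.

    Free parameters: equilibrium separation ``R_eq`` (pm), separation
    speed ``v`` (m/s, equal to pm/ps), dissociation onset ``t_d`` (ps),
    interaction angle ``theta`` (deg) and asymptotic internal energy
    ``E_a`` (eV).  Fixed physical inputs: the co-fragment dipole moment
    ``mu`` (debye), the ion charge (elementary charges) and the pump
    photon energy ``E_pump`` (eV).
    """

    r_eq_pm: float = 490.0
    v_m_per_s: float = 12.0
    t_d_ps: float = 51.0
    theta_deg: float = 38.0
    e_a_ev: float = 4.57
    mu_debye: float = 1.96
    q_e: float = 1.0
    e_pump_ev: float = 4.61

    def __post_init__(self) -> None:
        if not self.r_eq_pm > 0:
            raise ParameterError("r_eq_pm must be positive")
        if self.v_m_per_s < 0:
            raise ParameterError("v_m_per_s must be non-negative")

    @property
    def asymptote_ev(self) -> float:
        """TKER as R -> infinity: E_pump - E_a."""
        return self.e_pump_ev - self.e_a_ev

    def separation_pm(self, t_ps) -> np.ndarray:
        """Linear separation R(t) = R_eq + v (t - t_d); 1 m/s == 1 pm/ps."""
        t = np.asarray(t_ps, dtype=float)
        return self.r_eq_pm + self.v_m_per_s * (t - self.t_d_ps)

    def potential_ev(self, t_ps) -> np.ndarray:
        return ion_dipole_potential(
            self.separation_pm(t_ps), self.theta_deg, self.mu_debye, self.q_e
        )

    @property
    def v_eq_ev(self) -> float:
        """Identifiable amplitude V(R_eq, theta) of the potential term."""
        return float(ion_dipole_potential(self.r_eq_pm, self.theta_deg,
                                          self.mu_debye, self.q_e))


def tker_evolution(model: IonDipoleModel, t_ps, masked: bool = False):
    """TKER(t) = E_pump - E_a + V(R_eq + v (t - t_d)), in eV.

    Monotone non-increasing for ``v > 0`` and ``cos(theta) > 0``, with
    asymptote ``E_pump - E_a``.  Evaluation before the dissociation
    onset ``t_d`` is undefined; by default it raises, with
    ``masked=True`` those samples come back as NaN.
    """
    t = np.asarray(t_ps, dtype=float)
    early = t < model.t_d_ps
    if np.any(early):
        if not masked:
            raise PreconditionError(
                "TKER(t) is undefined before the dissociation onset t_d"
            )
        out = np.full(t.shape, np.nan)
        ok = ~early
        out[ok] = model.asymptote_ev + model.potential_ev(t[ok])
        return out
    return model.asymptote_ev + model.potential_ev(t)


@dataclass
class IonDipoleResults:
    """Five-parameter ion-dipole fit with uncertainties and correlations."""

    params: IonDipoleModel
    stderr: dict[str, float]
    correlations: dict[tuple[str, str], float]
    redchi: float
    nfev: int
    success: bool
    message: str
    model: "IonDipoleTKERModel" = field(repr=False)

    @property
    def v_eq_ev(self) -> float:
        """The identifiable combination V(R_eq, theta) (eV); R_eq and
        theta are not separately constrained by a mean-TKER curve."""
        return self.params.v_eq_ev

    def predict(self, t_ps) -> np.ndarray:
        return tker_evolution(self.params, t_ps)

    def to_dict(self) -> dict:
        p = self.params
        out = {
            "r_eq_pm": p.r_eq_pm,
            "v_m_per_s": p.v_m_per_s,
            "t_d_ps": p.t_d_ps,
            "theta_deg": p.theta_deg,
            "e_a_ev": p.e_a_ev,
            "mu_debye": p.mu_debye,
            "q_e": p.q_e,
            "e_pump_ev": p.e_pump_ev,
            "v_eq_ev": self.v_eq_ev,
            "asymptote_ev": p.asymptote_ev,
            "redchi": self.redchi,
            "success": self.success,
        }
        for k, v in self.stderr.items():
            out[f"{k}_stderr"] = v
        return {k: (float(v) if isinstance(v, (int, float)) else v)
                for k, v in out.items()}

    def summary(self) -> str:
        p = self.params
        lines = [
            "Ion-dipole mean-TKER fit",
            "=" * 46,
            f"reduced chi^2 = {self.redchi:.3f}   nfev = {self.nfev}",
            "-" * 46,
            f"R_eq  = {p.r_eq_pm:9.1f} +/- {self.stderr.get('r_eq_pm', math.nan):.1f} pm",
            f"v     = {p.v_m_per_s:9.2f} +/- {self.stderr.get('v_m_per_s', math.nan):.2f} m/s",
            f"t_d   = {p.t_d_ps:9.2f} +/- {self.stderr.get('t_d_ps', math.nan):.2f} ps",
            f"theta = {p.theta_deg:9.1f} +/- {self.stderr.get('theta_deg', math.nan):.1f} deg",
            f"E_a   = {p.e_a_ev:9.4f} +/- {self.stderr.get('e_a_ev', math.nan):.4f} eV",
            "-" * 46,
            f"V(R_eq, theta) = {self.v_eq_ev * 1e3:.1f} meV (identifiable amplitude)",
            f"asymptotic TKER = {p.asymptote_ev * 1e3:.1f} meV",
            "note: R_eq/theta and (R_eq, t_d) enter only through V(t);",
            "individual values depend on the start point along the flat",
            "directions (see correlations).",
        ]
        return "\n".join(lines)


class IonDipoleTKERModel:
    """Fit the ion-dipole model to a mean-TKER-versus-delay series.

    Parameters
    ----------
    delays_ps, mean_tker_mev : arrays
        The per-delay analytic means of the fitted statistical
        distributions, in meV.
    sigma_mev : array, optional
        1-sigma errors of the means (propagated from the
        Maxwell-Boltzmann fit covariance); uniform weights if omitted.
    """

    _FREE = ("r_eq_pm", "v_m_per_s", "t_d_ps", "theta_deg", "e_a_ev")

    def __init__(
        self,
        delays_ps,
        mean_tker_mev,
        sigma_mev=None,
        mu_debye: float = 1.96,
        q_e: float = 1.0,
        e_pump_ev: float = 4.61,
    ) -> None:
        self.delays_ps = np.asarray(delays_ps, dtype=float)
        self.tker_ev = np.asarray(mean_tker_mev, dtype=float) / 1e3
        if self.delays_ps.size < 8:
            raise PreconditionError("need at least 8 delay points")
        if sigma_mev is None:
            self.sigma_ev = np.ones_like(self.tker_ev) * 1e-3
        else:
            self.sigma_ev = np.asarray(sigma_mev, dtype=float) / 1e3
            if np.any(self.sigma_ev <= 0):
                raise ParameterError("sigma must be positive")
        self.mu_debye = mu_debye
        self.q_e = q_e
        self.e_pump_ev = e_pump_ev

    def _build(self, x: np.ndarray) -> IonDipoleModel:
        return IonDipoleModel(
            r_eq_pm=float(x[0]),
            v_m_per_s=float(abs(x[1])),
            t_d_ps=float(x[2]),
            theta_deg=float(x[3]),
            e_a_ev=float(x[4]),
            mu_debye=self.mu_debye,
            q_e=self.q_e,
            e_pump_ev=self.e_pump_ev,
        )

    def _k_ev_pm2(self, theta_deg: float) -> float:
        """Potential amplitude K = q mu cos(theta) / (4 pi eps0), eV pm^2."""
        return (
            self.q_e
            * E_CHARGE
            * self.mu_debye
            * DEBYE
            * math.cos(math.radians(theta_deg))
            / (4.0 * math.pi * EPSILON_0)
            / E_CHARGE
            * 1e24
        )

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        r_eq, v, t_d, theta, e_a = x
        r = r_eq + v * (self.delays_ps - t_d)
        model = self.e_pump_ev - e_a + self._k_ev_pm2(theta) / r**2
        return (model - self.tker_ev) / self.sigma_ev

    def _jacobian(self, x: np.ndarray) -> np.ndarray:
        # analytic derivatives: a finite-difference Jacobian's noise leaks
        # LM steps into the model's exactly-flat directions (R_eq/theta and
        # R_eq/t_d trade-offs), dragging individually-unidentifiable
        # parameters away from their assumed start values
        r_eq, v, t_d, theta, e_a = x
        dt = self.delays_ps - t_d
        r = r_eq + v * dt
        k = self._k_ev_pm2(theta)
        jac = np.empty((self.delays_ps.size, 5))
        jac[:, 0] = -2.0 * k / r**3
        jac[:, 1] = -2.0 * k * dt / r**3
        jac[:, 2] = 2.0 * k * v / r**3
        jac[:, 3] = -k * math.tan(math.radians(theta)) * math.pi / 180.0 / r**2
        jac[:, 4] = -1.0
        return jac / self.sigma_ev[:, None]

    def fit(self, init: IonDipoleModel | None = None) -> IonDipoleResults:
        if init is None:
            init = IonDipoleModel(
                mu_debye=self.mu_debye, q_e=self.q_e, e_pump_ev=self.e_pump_ev
            )
        t_min = float(self.delays_ps.min())
        if init.t_d_ps >= t_min:
            raise PreconditionError("initial t_d must precede the first delay")
        span = self.delays_ps.max() - init.t_d_ps
        if span < 2.0 * (t_min - init.t_d_ps):
            raise PreconditionError(
                "delays must span at least a factor 2 in (t - t_d)"
            )
        x0 = np.array(
            [init.r_eq_pm, init.v_m_per_s, init.t_d_ps, init.theta_deg, init.e_a_ev]
        )
        # bounded trust-region keeps the flat directions from walking into
        # unphysical territory (negative R_eq, theta beyond 90 deg)
        lower = [1.0, 0.0, -np.inf, 0.0, 0.0]
        upper = [np.inf, np.inf, t_min - 0.5, 89.0, self.e_pump_ev + 1.0]
        sol = least_squares(
            self._residuals,
            np.clip(x0, lower, upper),
            jac=self._jacobian,
            method="trf",
            bounds=(lower, upper),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        fitted = self._build(sol.x)
        ndata = self.delays_ps.size
        dof = max(ndata - 5, 1)
        redchi = float(2.0 * sol.cost / dof)
        # covariance via pseudo-inverse: J^T J is rank-deficient along the
        # two flat directions, whose variances are reported as inf below
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj, rcond=1e-10) * redchi
        d = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {name: float(d[i]) for i, name in enumerate(self._FREE)}
        corr: dict[tuple[str, str], float] = {}
        for i, ni in enumerate(self._FREE):
            for j in range(i + 1, len(self._FREE)):
                if d[i] > 0 and d[j] > 0:
                    corr[(ni, self._FREE[j])] = float(cov[i, j] / (d[i] * d[j]))
        return IonDipoleResults(
            params=fitted,
            stderr=stderr,
            correlations=corr,
            redchi=redchi,
            nfev=int(sol.nfev),
            success=bool(sol.success),
            message=str(sol.message),
            model=self,
        )


def fit_ion_dipole(
    delays_ps,
    mean_tker_mev,
    sigma_mev=None,
    init: IonDipoleModel | None = None,
    **fixed,
) -> IonDipoleResults:
    """Convenience wrapper: build an :class:`IonDipoleTKERModel` and fit."""
    model = IonDipoleTKERModel(delays_ps, mean_tker_mev, sigma_mev, **fixed)
    return model.fit(init=init)
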