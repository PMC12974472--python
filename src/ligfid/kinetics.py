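"""Steady-state fidelity analysis for DNA ligase variants.

Initial rates are taken as slopes of straight-line fits to early time points
(product fraction below 0.20 by default, free intercept).  Rates per active
enzyme over a substrate grid are fit with the Michaelis–Menten equation

    v0 / [E] = k_cat [S] / (K_M + [S])

by unweighted nonlinear least squares.  Fidelity statistics derive from the
fitted parameters: the abortive fraction (rate of AMP-DNA release over total
product rate), the fraction ligated F_lig = 1 - abortive fraction, the
discrimination factor (catalytic efficiency on the canonical substrate over
efficiency on the damaged one), and fold changes between a reference and a
variant enzyme.  Active-site titration — single-turnover product amplitude
versus nominal enzyme — is fit with a continuous two-segment model
``y = a * min(x, x0)`` whose rising slope ``a`` is the active fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RatePoint",
    "MichaelisFit",
    "FidelityReport",
    "TitrationResult",
    "FitError",
    "WindowTooShortError",
    "initial_rate",
    "turnovers",
    "fit_michaelis_menten",
    "abortive_fraction",
    "discrimination",
    "fidelity_report",
    "active_site_titration",
    "round_sig",
]


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or is unidentifiable."""


class WindowTooShortError(ValueError):
    """Fewer than three time points qualify for the initial-rate window."""


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class RatePoint:
    """An initial rate at one substrate concentration.

    ``v0`` in nM/s; ``v0_per_enzyme`` (per s) is ``v0 / enzyme_conc``.
    ``species`` is one of ``sealed``, ``intermediate``, ``total``.
    """

    substrate_conc: float
    v0: float
    enzyme_conc: float
    species: str = "sealed"
    n_points_used: int = 0
    condition: str = ""

    def __post_init__(self):
        if self.v0 < 0:
            raise ValueError("v0 must be >= 0")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be > 0")
        if self.species not in ("sealed", "intermediate", "total"):
            raise ValueError(f"unknown species {self.species!r}")

    @property
    def v0_per_enzyme(self) -> float:
        return self.v0 / self.enzyme_conc


@dataclass(frozen=True)
class MichaelisFit:
    """Fitted steady-state parameters.

    ``catalytic_efficiency`` is always ``k_cat / K_M`` (per nM per s),
    computed, never fit independently.
    """

    k_cat: float
    K_M: float
    k_cat_se: float = float("nan")
    K_M_se: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0
    poorly_determined: bool = False
    condition: str = ""

    def __post_init__(self):
        if self.k_cat <= 0 or self.K_M <= 0:
            raise ValueError("k_cat and K_M must be > 0 on a successful fit")

    @property
    def catalytic_efficiency(self) -> float:
        return self.k_cat / self.K_M

    def confidence_interval(self, param: str, level: float = 0.95):
        """t-based confidence interval for ``k_cat`` or ``K_M``."""
        est, se = ((self.k_cat, self.k_cat_se) if param == "k_cat"
                   else (self.K_M, self.K_M_se))
        dof = max(self.n_points - 2, 1)
        half = stats.t.ppf(0.5 + level / 2, dof) * se
        return est - half, est + half


def initial_rate(
    times,
    concentrations,
    substrate_conc: float,
    enzyme_conc: float,
    species: str = "sealed",
    max_fraction: float = 0.20,
    condition: str = "",
) -> RatePoint:
    """Initial rate from early time points of a progress curve.

    Points where ``concentration / substrate_conc < max_fraction`` enter an
    unweighted straight-line fit with free intercept; the slope is v0.  At
    least three qualifying points are required.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and concentrations must be matching 1-D arrays")
    mask = y / substrate_conc < max_fraction
    if mask.sum() < 3:
        raise WindowTooShortError(
            f"only {int(mask.sum())} points below fraction {max_fraction} "
            f"for condition {condition!r}; need >= 3")
    slope = float(np.polyfit(t[mask], y[mask], 1)[0])
    return RatePoint(substrate_conc=float(substrate_conc),
                     v0=max(slope, 0.0), enzyme_conc=float(enzyme_conc),
                     species=species, n_points_used=int(mask.sum()),
                     condition=condition)


def turnovers(product_conc, enzyme_conc: float) -> np.ndarray:
    """Product concentration expressed as turnovers, P(t) / [E]."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")
    return np.asarray(product_conc, dtype=float) / enzyme_conc


def _sandwich_se(s, resid, kcat, km):
    """Heteroscedasticity-robust (HC3) standard errors for the MM fit.

    Band-intensity noise is multiplicative, so residual variance grows with
    the rate; the plain least-squares covariance understates the k_cat
    uncertainty.  The sandwich estimator keeps the unweighted point
    estimates while giving honest standard errors.
    """
    J = np.column_stack([s / (km + s), -kcat * s / (km + s) ** 2])
    JtJinv = np.linalg.inv(J.T @ J)
    lev = np.einsum("ij,jk,ik->i", J, JtJinv, J)
    w = resid ** 2 / np.clip(1.0 - lev, 1e-8, None) ** 2
    cov = JtJinv @ (J.T * w) @ J @ JtJinv
    return np.sqrt(np.diag(cov))


def fit_michaelis_menten(points, condition: str = "") -> MichaelisFit:
    """Unweighted nonlinear least-squares Michaelis–Menten fit.

    ``points`` is a sequence of :class:`RatePoint`; replicate points enter
    individually.  Fits v0/[E] versus [S]; point estimates are unweighted,
    standard errors are heteroscedasticity-robust (HC3 sandwich).  Warns
    when fewer than four distinct substrate concentrations are available or
    the grid does not bracket the K_M estimate; flags K_M beyond 10x the
    largest [S] as poorly determined.
    """
    points = list(points)
    s = np.array([p.substrate_conc for p in points], dtype=float)
    v = np.array([p.v0_per_enzyme for p in points], dtype=float)
    if len(np.unique(s)) < 4:
        warnings.warn("fewer than 4 distinct substrate concentrations; "
                      "K_M may be poorly constrained", stacklevel=2)

    def mm(sv, kcat, km):
        return kcat * sv / (km + sv)

    vmax0 = max(v.max(), 1e-12)
    half = vmax0 / 2
    km0 = float(s[np.argmin(np.abs(v - half))]) or float(np.median(s))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                mm, s, v, p0=[1.2 * vmax0, km0],
                bounds=([0, 0], [np.inf, np.inf]), maxfev=20000,
                x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit failed for {condition!r}: {exc}")
    kcat, km = popt
    if kcat <= 0 or km <= 0 or not np.all(np.isfinite(popt)):
        raise FitError(f"non-physical Michaelis-Menten solution for {condition!r}")
    resid = v - mm(s, *popt)
    se = _sandwich_se(s, resid, kcat, km)
    if not np.all(np.isfinite(se)):
        se = (np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov))
              else np.array([np.nan, np.nan]))
    poorly = bool(km > 10 * s.max())
    if not (s.min() < km < s.max()):
        warnings.warn(f"substrate grid does not bracket fitted K_M = {km:.3g} nM",
                      stacklevel=2)
    return MichaelisFit(k_cat=float(kcat), K_M=float(km),
                        k_cat_se=float(se[0]), K_M_se=float(se[1]),
                        rss=float(resid @ resid), n_points=len(points),
                        poorly_determined=poorly, condition=condition)


def abortive_fraction(v_intermediate: RatePoint, v_sealed: RatePoint) -> float:
    """Fraction of abortive ligation from initial rates.

    v_I / (v_I + v_P): the rate of AMP-DNA release over the total rate of
    product formation, per the initial-rate definition.
    """
    if v_intermediate.condition != v_sealed.condition:
        raise ValueError(
            f"mismatched conditions: {v_intermediate.condition!r} vs "
            f"{v_sealed.condition!r}")
    total = v_intermediate.v0 + v_sealed.v0
    if total <= 0:
        raise ValueError("total rate must be > 0")
    return v_intermediate.v0 / total


def abortive_fraction_endpoint(intermediate_conc: float, sealed_conc: float) -> float:
    """Endpoint-concentration variant of the abortive fraction (non-default)."""
    total = intermediate_conc + sealed_conc
    if total <= 0:
        raise ValueError("total product must be > 0")
    return intermediate_conc / total


def discrimination(fit_canonical: MichaelisFit, fit_damaged: MichaelisFit) -> float:
    """Discrimination factor: efficiency(canonical) / efficiency(damaged).

    Unitless; invariant to a common rescaling of concentration units.
    Returns ``inf`` when the damaged-substrate efficiency is zero.
    """
    eff_d = fit_damaged.catalytic_efficiency
    if eff_d == 0:
        warnings.warn("zero damaged-substrate efficiency: infinite discrimination",
                      stacklevel=2)
        return float("inf")
    return fit_canonical.catalytic_efficiency / eff_d


@dataclass(frozen=True)
class FidelityReport:
    """All derived fidelity statistics for a reference/variant enzyme pair.

    Fold changes are reference/variant (>1 means the variant is impaired);
    relative parameters are variant/reference (reference = 1).  Values are
    carried at full precision; :meth:`table` rounds to 2 significant
    figures for presentation.
    """

    fits: dict = field(repr=False)                 # (enzyme, substrate) -> MichaelisFit
    abortive: dict = field(repr=False)             # (enzyme, substrate) -> fraction
    reference: str = "reference"
    variant: str = "variant"
    canonical: str = "canonical"
    damaged: str = "damaged"

    # derived (filled by fidelity_report)
    kcat_fold: dict = field(default_factory=dict)
    km_fold: dict = field(default_factory=dict)
    efficiency_fold: dict = field(default_factory=dict)
    relative_kcat: dict = field(default_factory=dict)
    relative_efficiency: dict = field(default_factory=dict)
    discrimination_by_enzyme: dict = field(default_factory=dict)
    fidelity_increase: float = float("nan")
    f_lig: dict = field(default_factory=dict)
    f_lig_ratio: dict = field(default_factory=dict)
    abortive_fold: dict = field(default_factory=dict)

    def table(self, sig: int = 2) -> dict:
        """Presentation values rounded to ``sig`` significant figures."""
        r = lambda x: round_sig(x, sig)
        return {
            "kcat_fold_decrease": {k: r(v) for k, v in self.kcat_fold.items()},
            "km_fold_increase": {k: r(v) for k, v in self.km_fold.items()},
            "efficiency_fold_decrease": {k: r(v) for k, v in self.efficiency_fold.items()},
            "relative_kcat": {k: r(v) for k, v in self.relative_kcat.items()},
            "relative_efficiency": {k: r(v) for k, v in self.relative_efficiency.items()},
            "discrimination": {k: r(v) for k, v in self.discrimination_by_enzyme.items()},
            "fidelity_increase": r(self.fidelity_increase),
            "f_lig_ratio": {k: r(v) for k, v in self.f_lig_ratio.items()},
            "abortive_fold_increase": {k: r(v) for k, v in self.abortive_fold.items()},
        }


def fidelity_report(
    fits: dict,
    abortive: dict,
    reference: str = "reference",
    variant: str = "variant",
    canonical: str = "canonical",
    damaged: str = "damaged",
) -> FidelityReport:
    """Assemble the full fidelity report for a 2x2 enzyme x substrate design.

    ``fits`` maps ``(enzyme, substrate)`` to :class:`MichaelisFit` and
    ``abortive`` maps the same keys to abortive fractions; all four cells of
    ``{reference, variant} x {canonical, damaged}`` must be present in
    ``fits`` (abortive fractions may cover a subset, but the damaged cells
    are needed for the F_lig ratio).
    """
    enzymes = (reference, variant)
    substrates = (canonical, damaged)
    missing = [(e, s) for e in enzymes for s in substrates if (e, s) not in fits]
    if missing:
        raise ValueError(f"incomplete 2x2 design; missing fit cells: {missing}")

    kcat_fold, km_fold, eff_fold = {}, {}, {}
    rel_kcat, rel_eff = {}, {}
    for s in substrates:
        ref, var = fits[(reference, s)], fits[(variant, s)]
        kcat_fold[s] = ref.k_cat / var.k_cat
        km_fold[s] = var.K_M / ref.K_M
        eff_fold[s] = ref.catalytic_efficiency / var.catalytic_efficiency
        rel_kcat[s] = var.k_cat / ref.k_cat
        rel_eff[s] = var.catalytic_efficiency / ref.catalytic_efficiency

    disc = {e: discrimination(fits[(e, canonical)], fits[(e, damaged)])
            for e in enzymes}
    fidelity_increase = disc[variant] / disc[reference]

    f_lig = {key: 1.0 - frac for key, frac in abortive.items()}
    f_lig_ratio, abortive_fold = {}, {}
    for s in substrates:
        if (reference, s) in abortive and (variant, s) in abortive:
            if f_lig[(variant, s)] > 0:
                f_lig_ratio[s] = f_lig[(reference, s)] / f_lig[(variant, s)]
            else:
                f_lig_ratio[s] = float("inf")
            if abortive[(reference, s)] > 0:
                abortive_fold[s] = abortive[(variant, s)] / abortive[(reference, s)]

    return FidelityReport(
        fits=dict(fits), abortive=dict(abortive),
        reference=reference, variant=variant,
        canonical=canonical, damaged=damaged,
        kcat_fold=kcat_fold, km_fold=km_fold, efficiency_fold=eff_fold,
        relative_kcat=rel_kcat, relative_efficiency=rel_eff,
        discrimination_by_enzyme=disc, fidelity_increase=fidelity_increase,
        f_lig=f_lig, f_lig_ratio=f_lig_ratio, abortive_fold=abortive_fold,
    )


@dataclass(frozen=True)
class TitrationResult:
    """Result of a segmental linear regression on an active-site titration."""

    active_fraction: float
    breakpoint: float
    plateau: float
    rss: float
    flagged_above_one: bool = False

    @property
    def percent_active(self) -> int:
        return int(round(self.active_fraction * 100))


def _two_segment_rss(x, y, x0):
    """Best slope and RSS of y = a*min(x, x0) for a fixed breakpoint."""
    m = np.minimum(x, x0)
    denom = m @ m
    a = (m @ y) / denom if denom > 0 else 0.0
    r = y - a * m
    return a, float(r @ r)


def active_site_titration(nominal_enzyme, product) -> TitrationResult:
    """Fit the two-segment titration model and return the active fraction.

    The model is continuous piecewise-linear through the origin,
    ``y = a*x`` below the breakpoint ``x0`` and a hard plateau ``a*x0``
    above it.  The slope ``a`` is the active fraction; the plateau estimates
    the DNA concentration.  Breakpoints are profiled over every interval
    between sampled enzyme concentrations (ties assigned to the rising
    segment) and refined by bounded scalar minimisation.

    Raises :class:`FitError` when the breakpoint is not bracketed by the
    sampled range (titration unidentifiable).
    """
    x = np.asarray(nominal_enzyme, dtype=float)
    y = np.asarray(product, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("need matching 1-D arrays with >= 4 titration points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(x <= 0):
        raise ValueError("nominal enzyme concentrations must be > 0")

    best = (np.inf, None, None)  # rss, a, x0
    xs = np.unique(x)
    edges = np.concatenate([[xs[0] * 0.5], xs, [xs[-1] * 1.5]])
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            lambda x0: _two_segment_rss(x, y, x0)[1],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10 * xs[-1]})
        a, rss = _two_segment_rss(x, y, float(res.x))
        if rss < best[0]:
            best = (rss, a, float(res.x))
    rss, a, x0 = best
    if not (xs[0] < x0 < xs[-1]):
        raise FitError(
            f"titration breakpoint {x0:.3g} nM outside sampled range "
            f"[{xs[0]:g}, {xs[-1]:g}]; titration unidentifiable")
    flagged = a > 1.1
    if flagged:
        warnings.warn(f"active fraction {a:.3f} exceeds 1.1", stacklevel=2)
    return TitrationResult(active_fraction=float(a), breakpoint=x0,
                           plateau=float(a * x0), rss=rss,
                           flagged_above_one=flagged)
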