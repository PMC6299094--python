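"""Non-imaging quantitations: standard curves, reduction kinetics,
clearance, survival, macrorheology summaries and shared group statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .stats_utils import holm_sidak
from .microrheology import one_way_anova

__all__ = [
    "StandardCurve",
    "KineticsFit",
    "standard_curve_concentration",
    "dtnb_rate",
    "rate_ratio",
    "acute_endogenous_clearance",
    "survival_chisq",
    "linear_regime_viscosity",
    "viscosity_mass_regression",
    "group_compare",
]


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    calibration_range: tuple[float, float]

    def concentration(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


@dataclass
class KineticsFit:
    rate_constant: float  # 1/s
    amplitude: float
    baseline: float
    rmse: float

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be non-negative")


def fit_standard_curve(standards) -> StandardCurve:
    """OLS line through (concentration, absorbance) standard pairs."""
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absb = np.asarray([s[1] for s in standards], dtype=float)
    if len(conc) < 3:
        raise ValueError("need at least 3 standards")
    res = stats.linregress(conc, absb)
    if abs(res.slope) < 1e-12:
        raise ValueError("degenerate standard curve (|slope| ~ 0)")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        calibration_range=(float(conc.min()), float(conc.max())),
    )


def standard_curve_concentration(standards, unknowns) -> tuple[np.ndarray, StandardCurve, list[bool]]:
    """Interpolate unknown concentrations along a linear standard curve.

    ``unknowns`` is a sequence of replicate-absorbance sequences (e.g.
    duplicates); replicates are averaged before inversion.  Returns the
    concentrations, the fitted curve and an extrapolation flag per unknown.
    """
    curve = fit_standard_curve(standards)
    lo_a = curve.intercept + curve.slope * curve.calibration_range[0]
    hi_a = curve.intercept + curve.slope * curve.calibration_range[1]
    lo_a, hi_a = min(lo_a, hi_a), max(lo_a, hi_a)
    concs, extrap = [], []
    for reps in unknowns:
        a = float(np.mean(np.atleast_1d(np.asarray(reps, dtype=float))))
        concs.append(curve.concentration(a))
        extrap.append(not (lo_a <= a <= hi_a))
    return np.asarray(concs), curve, extrap


def dtnb_rate(times, absorbance) -> KineticsFit:
    """Pseudo-first-order fit of product formation.

    Model: ``A(t) = baseline + amplitude * (1 - exp(-k t))``, nonlinear
    least squares.  A flat series short-circuits to k = 0, amplitude = 0.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    span = np.ptp(a)
    if span < 1e-12 or span < 1e-6 * max(abs(a).max(), 1.0):
        return KineticsFit(0.0, 0.0, float(a.mean()),
                           float(np.sqrt(np.mean((a - a.mean()) ** 2))))

    def model(t, k, amp, base):
        return base + amp * (1 - np.exp(-k * t))

    t_span = t[-1] - t[0]
    p0 = (1.0 / max(t_span / 3, 1e-9), span, a[0])
    try:
        popt, _ = optimize.curve_fit(
            model, t, a, p0=p0,
            bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as e:
        raise RuntimeError(f"kinetics fit failed to converge (initial guess {p0})") from e
    resid = a - model(t, *popt)
    return KineticsFit(float(popt[0]), float(popt[1]), float(popt[2]),
                       float(np.sqrt(np.mean(resid**2))))


def rate_ratio(fit_a: KineticsFit, fit_b: KineticsFit) -> float:
    """Ratio of rate constants a / b (compares two reducing agents)."""
    if fit_b.rate_constant == 0:
        raise ZeroDivisionError("denominator rate constant is zero")
    return fit_a.rate_constant / fit_b.rate_constant


def acute_endogenous_clearance(vehicle, treated, test: str = "welch_t") -> dict:
    """Percent decrease of mean leukocyte counts, treated vs vehicle, with a
    two-sided group comparison (Welch t by default, Mann-Whitney optional)."""
    v = np.asarray(vehicle, dtype=float)
    tr = np.asarray(treated, dtype=float)
    if len(v) < 2 or len(tr) < 2:
        raise ValueError("need at least 2 animals per arm")
    flags = {}
    if v.mean() == 0:
        flags["percent_decrease"] = "vehicle mean is zero: percent undefined"
        pct = np.nan
    else:
        pct = 100.0 * (v.mean() - tr.mean()) / v.mean()
    if test == "welch_t":
        stat, p = stats.ttest_ind(v, tr, equal_var=False)
    elif test == "mann_whitney":
        stat, p = stats.mannwhitneyu(v, tr, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    if not np.isfinite(p):
        p = 1.0
    return {
        "percent_decrease": float(pct) if np.isfinite(pct) else None,
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "flags": flags,
    }


def survival_chisq(groups) -> tuple[float, int, float]:
    """Pearson chi-square on a groups x {died, survived} table.

    ``groups`` is a sequence of (deaths, total) pairs.  Returns
    (chi2, df, p); a warning is attached when any expected cell is < 1.
    """
    deaths = np.asarray([g[0] for g in groups], dtype=float)
    totals = np.asarray([g[1] for g in groups], dtype=float)
    if len(deaths) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(totals <= 0):
        raise ValueError("group totals must be positive")
    if np.any(deaths > totals) or np.any(deaths < 0):
        raise ValueError("deaths must be within [0, total]")
    table = np.column_stack([deaths, totals - deaths])
    col_tot = table.sum(axis=0)
    if np.any(col_tot == 0):  # all died or none died: no variation to test
        return 0.0, len(deaths) - 1, 1.0
    expected = np.outer(totals, col_tot) / totals.sum()
    if np.any(expected < 1):
        warnings.warn("expected cell count below 1; chi-square approximation is poor")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = len(deaths) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def linear_regime_viscosity(
    stress, modulus_magnitude, frequency: float, tolerance: float = 0.10
) -> tuple[float, dict]:
    """Complex viscosity from the linear regime of a fixed-frequency stress
    sweep.

    The linear regime is the longest leading run over which the modulus
    stays within ``tolerance`` of its running median; the run ends at the
    first of two consecutive violations, so a single noise outlier does not
    truncate the plateau.  The complex viscosity is the plateau modulus
    divided by the angular frequency.
    """
    s = np.asarray(stress, dtype=float)
    g = np.asarray(modulus_magnitude, dtype=float)
    if len(s) < 5:
        raise ValueError("need at least 5 sweep points")
    if np.any(np.diff(s) < 0):
        raise ValueError("sweep must be sorted by stress")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    n_plateau = 1
    for i in range(1, len(g)):
        med = np.median(g[:i])
        if abs(g[i] - med) > tolerance * med:
            next_bad = i + 1 >= len(g) or abs(g[i + 1] - med) > tolerance * med
            if next_bad:
                break
        n_plateau = i + 1
    if n_plateau < 3:
        raise ValueError("no linear regime (plateau shorter than 3 points)")
    plateau = float(np.mean(g[:n_plateau]))
    return plateau / frequency, {"n_plateau": n_plateau, "plateau_modulus": plateau}


def viscosity_mass_regression(pairs) -> dict:
    """OLS of complex viscosity on molecular mass with Pearson r and p."""
    m = np.asarray([p[0] for p in pairs], dtype=float)
    v = np.asarray([p[1] for p in pairs], dtype=float)
    if len(m) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(m) == 0:
        raise ValueError("zero variance in mass")
    res = stats.linregress(m, v)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
    }


def group_compare(
    groups: dict,
    method: str = "welch_t",
    alternative: str = "two-sided",
) -> dict:
    """Shared group-comparison front end.

    Methods: ``welch_t`` (two groups), ``mann_whitney`` (two groups, exact
    where scipy chooses it), ``anova_holm_sidak`` (any number of groups:
    one-way ANOVA plus all-pairs Welch comparisons with Holm-Sidak
    family-wise adjustment).
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    report: dict = {"method": method, "alternative": alternative, "groups": names}

    if method in ("welch_t", "mann_whitney"):
        if len(names) != 2:
            raise ValueError(f"{method} requires exactly 2 groups")
        a, b = arrays[names[0]], arrays[names[1]]
        if method == "welch_t":
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
                report.update(statistic=0.0, p=1.0,
                              note="identical degenerate groups")
                return report
            stat, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        else:
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                report.update(statistic=float(len(a) * len(b) / 2), p=1.0,
                              note="all values tied: midrank U, p set to 1")
                return report
            stat, p = stats.mannwhitneyu(a, b, alternative=alternative)
        report.update(statistic=float(stat), p=float(p))
        return report

    if method == "anova_holm_sidak":
        f, dfb, dfw, p = one_way_anova([arrays[n] for n in names])
        pairs, raw = [], []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = arrays[names[i]], arrays[names[j]]
                if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
                    pv, tstat = 1.0, 0.0
                else:
                    tstat, pv = stats.ttest_ind(a, b, equal_var=False)
                    if not np.isfinite(pv):
                        pv = 1.0
                pairs.append((names[i], names[j], float(tstat)))
                raw.append(float(pv))
        adj = holm_sidak(raw)
        report.update(
            F=f, df=(dfb, dfw), p=p,
            pairwise=[
                {"a": a, "b": b, "t": t, "p_raw": pr, "p_adjusted": pa}
                for (a, b, t), pr, pa in zip(pairs, raw, adj)
            ],
        )
        return report

    raise ValueError(f"unknown method {method!r}")
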