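"""Fibrillar-collagen quantification and stereology.

Area fractions from thresholded SHG fields, Cavalieri volume estimation,
point counting, least-chi-square Gaussian-mixture histogram fitting, and
the one-sided rejection-region t comparison used for histogram pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AreaFractionRecord",
    "MixtureFit",
    "RejectionRegionResult",
    "collagen_area_fraction",
    "normalize_to_volume",
    "cavalieri_volume",
    "point_count_fraction",
    "fit_gaussian_mixture_histogram",
    "rejection_region_test",
    "rejection_region_critical_value",
]


@dataclass
class AreaFractionRecord:
    animal_id: str
    group_id: str
    field_id: str
    percent_area: float
    lung_volume: float | None = None
    normalized_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent_area <= 100:
            raise ValueError("percent_area must be in [0, 100]")


@dataclass
class MixtureFit:
    n_peaks: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray  # component masses in count units
    chi2: float
    dof: int
    chi2_trace: dict  # k -> (chi2, dof)

    def __post_init__(self) -> None:
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")


@dataclass
class RejectionRegionResult:
    t_statistic: float
    df: float
    critical_value: float
    decision: bool
    alpha: float
    flags: dict


def collagen_area_fraction(
    field: np.ndarray,
    threshold: float | str = "otsu",
    fallback_threshold: float = 0.5,
) -> float:
    """Percent of pixels above threshold.

    ``threshold`` is either a fixed numeric value or ``"otsu"``; a constant
    image defeats Otsu and falls back to ``fallback_threshold`` with a
    warning.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2:
        raise ValueError("field must be a single-channel 2-D image")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(field) == 0:
            warnings.warn("constant image: Otsu undefined, using fallback threshold")
            thr = fallback_threshold
        else:
            from skimage.filters import threshold_otsu

            thr = threshold_otsu(field)
    else:
        thr = float(threshold)
    return float(100.0 * np.mean(field > thr))


def normalize_to_volume(
    records: pd.DataFrame,
    reference_volume: float | None = None,
    mode: str = "multiply",
) -> pd.DataFrame:
    """Attach volume-normalized fractions to area-fraction records.

    ``records`` needs ``percent_area`` and ``lung_volume`` columns.  The
    default rule scales each record by ``lung_volume / reference_volume``
    (reference defaults to the cohort mean volume); ``mode="divide"``
    applies the reciprocal.
    """
    if (records["lung_volume"] <= 0).any():
        raise ValueError("lung volumes must be positive")
    out = records.copy()
    if reference_volume is None:
        reference_volume = float(records["lung_volume"].mean())
    if reference_volume <= 0:
        raise ValueError("reference_volume must be positive")
    ratio = out["lung_volume"] / reference_volume
    if mode == "divide":
        ratio = 1.0 / ratio
    elif mode != "multiply":
        raise ValueError("mode must be 'multiply' or 'divide'")
    out["normalized_fraction"] = out["percent_area"] * ratio
    return out


def cavalieri_volume(slice_areas, slice_thickness: float) -> float:
    """Volume as section spacing times the summed section areas."""
    areas = np.asarray(slice_areas, dtype=float)
    if areas.size < 1:
        raise ValueError("need at least one slice")
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be positive")
    if np.any(areas < 0):
        raise ValueError("slice areas must be non-negative")
    return float(slice_thickness * areas.sum())


def point_count_fraction(
    field: np.ndarray,
    grid_spacing: int,
    threshold: float = 0.5,
    seed: int | None = 0,
) -> float:
    """Fraction of grid points landing on foreground.

    The grid offset is randomized by ``seed``, which makes the estimator
    unbiased over offsets for any structure.
    """
    field = np.asarray(field)
    if grid_spacing < 1:
        raise ValueError("grid_spacing must be >= 1")
    if grid_spacing > min(field.shape):
        raise ValueError("grid coarser than the image")
    rng = np.random.default_rng(seed)
    oy, ox = rng.integers(0, grid_spacing, 2)
    hits = field[oy::grid_spacing, ox::grid_spacing]
    if hits.size == 0:
        raise ValueError("grid selects no points")
    if field.dtype == bool:
        return float(hits.mean())
    return float((hits > threshold).mean())


# ---------------------------------------------------------------------------
# histogram mixture fitting
# ---------------------------------------------------------------------------


def _mixture_counts(centers: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Evaluate a sum of Gaussians parameterized as (amp, mean, sd) triples."""
    out = np.zeros_like(centers)
    for j in range(len(params) // 3):
        a, mu, sd = params[3 * j : 3 * j + 3]
        out += a * np.exp(-((centers - mu) ** 2) / (2 * sd**2))
    return out


def _chi2(counts: np.ndarray, fit: np.ndarray) -> float:
    return float(np.sum((counts - fit) ** 2 / np.maximum(fit, 1.0)))


def _fit_k(
    centers: np.ndarray, counts: np.ndarray, inits: list[np.ndarray]
) -> tuple[np.ndarray, float] | None:
    span = centers[-1] - centers[0]
    best = None
    for p0 in inits:
        k = len(p0) // 3
        lb = np.tile([0.0, centers[0] - span, 1e-3], k)
        ub = np.tile([np.inf, centers[-1] + span, 10 * span + 1], k)
        try:
            res = optimize.least_squares(
                lambda p: (counts - _mixture_counts(centers, p))
                / np.sqrt(np.maximum(_mixture_counts(centers, p), 1.0)),
                np.clip(p0, lb, ub),
                bounds=(lb, ub),
                max_nfev=2000,
            )
        except Exception:
            continue
        chi2 = _chi2(counts, _mixture_counts(centers, res.x))
        if best is None or chi2 < best[1]:
            best = (res.x, chi2)
    return best


def fit_gaussian_mixture_histogram(
    values,
    max_peaks: int = 3,
    bin_rule: str = "fd",
    improvement_threshold: float = 0.15,
) -> MixtureFit:
    """Least-chi-square Gaussian-sum fit to a histogram of percent areas.

    For k = 1..max_peaks a k-component Gaussian sum is fitted to the bin
    counts by nonlinear least squares minimizing
    ``sum (obs - fit)^2 / max(fit, 1)``; the selected k is the smallest
    whose reduced chi-square is not improved by more than
    ``improvement_threshold`` by k+1 components.  Each k+1 fit is also
    started from the k solution (plus a vanishing extra component), which
    keeps chi-square non-increasing in k.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 30:
        raise ValueError("need at least 30 values for a stable histogram")
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    edges = np.histogram_bin_edges(values, bins=bin_rule)
    counts, _ = np.histogram(values, bins=edges)
    counts = counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]

    fits: dict[int, tuple[np.ndarray, float]] = {}
    qs = np.quantile(values, np.linspace(0, 1, max_peaks + 2)[1:-1])
    for k in range(1, max_peaks + 1):
        inits = []
        # quantile-chunk initialization
        chunks = np.array_split(np.sort(values), k)
        p0 = []
        for c in chunks:
            sd = max(c.std(), bin_width / 2, 1e-3)
            amp = len(c) * bin_width / (sd * np.sqrt(2 * np.pi))
            p0.extend([amp, c.mean(), sd])
        inits.append(np.array(p0))
        if k - 1 in fits:  # nested start: previous best + tiny extra peak
            prev = fits[k - 1][0]
            extra = np.array([1e-6, float(qs[min(k - 1, len(qs) - 1)]),
                              max(bin_width, 1e-3)])
            inits.append(np.concatenate([prev, extra]))
        best = _fit_k(centers, counts, inits)
        if best is None:
            warnings.warn(f"mixture fit with k={k} failed to converge; skipped")
            continue
        fits[k] = best
    if not fits:
        raise RuntimeError("all mixture fits failed")

    def red(k: int) -> float:
        dof = max(1, len(counts) - 3 * k)
        return fits[k][1] / dof

    ks = sorted(fits)
    selected = ks[-1]
    for i, k in enumerate(ks[:-1]):
        nxt = ks[i + 1]
        # stop when the fit is already at the counting-noise floor (reduced
        # chi2 within 3 sigma of 1): extra components then only chase noise
        dof_k = max(1, len(counts) - 3 * k)
        noise_floor = 1.0 + 3.0 * np.sqrt(2.0 / dof_k)
        if red(k) <= noise_floor or red(nxt) >= red(k) * (1 - improvement_threshold):
            selected = k
            break

    params, chi2 = fits[selected]
    k = selected
    amps = params[0::3][:k]
    means = params[1::3][:k]
    sds = params[2::3][:k]
    order = np.argsort(means)
    weights = amps * sds * np.sqrt(2 * np.pi) / bin_width  # component mass
    return MixtureFit(
        n_peaks=k,
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        chi2=chi2,
        dof=max(1, len(counts) - 3 * k),
        chi2_trace={kk: (fits[kk][1], max(1, len(counts) - 3 * kk)) for kk in fits},
    )


# ---------------------------------------------------------------------------
# rejection-region comparison
# ---------------------------------------------------------------------------


def rejection_region_critical_value(alpha: float = 0.001, df: float = np.inf) -> float:
    """Upper one-sided critical value; the standard-normal limit is used for
    df > 100 (t and z agree to two decimals there)."""
    if df > 100:
        return float(stats.norm.ppf(1 - alpha))
    return float(stats.t.ppf(1 - alpha, df))


def rejection_region_test(
    group_a,
    group_b,
    alpha: float = 0.001,
    welch: bool = True,
) -> RejectionRegionResult:
    """One-sided two-sample t comparison against a fixed rejection region.

    The statistic is ``mean(b) - mean(a)`` standardized (Welch by default,
    pooled otherwise); the decision is ``t >= critical_value`` where the
    critical value is the upper-``alpha`` quantile of the reference
    distribution (normal limit for df > 100).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    flags: dict = {}
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            flags["t"] = "zero variance and equal means: t undefined"
            return RejectionRegionResult(np.nan, na + nb - 2,
                                         rejection_region_critical_value(alpha, na + nb - 2),
                                         False, alpha, flags)
        t = np.inf if b.mean() > a.mean() else -np.inf
        df = na + nb - 2
    elif welch:
        se2 = va / na + vb / nb
        t = (b.mean() - a.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    crit = rejection_region_critical_value(alpha, df)
    return RejectionRegionResult(float(t), float(df), crit, bool(t >= crit), alpha, flags)
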