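"""Functional metrics from B-scan time series.

Four quantities are extracted from a depth-resolved reflectance stack:
airway-surface-liquid (ASL) depth, periciliary-layer (PCL) depth, ciliary
beat frequency (CBF) from the reflectance power spectrum of the ciliated
band, and mucociliary transport (MCT) rate from the streak slope of a
kymograph built within 50 um above the epithelial surface.

Depth increases downward (row index grows toward tissue); "above the
surface" therefore means smaller row indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import ImageStack

__all__ = [
    "LayerDepths",
    "CBFEstimate",
    "Kymograph",
    "MCTEstimate",
    "FunctionalMetrics",
    "measure_layer_depths",
    "estimate_cbf",
    "build_kymograph",
    "estimate_mct_rate",
    "analyze_stack",
]

KYMO_BAND_UM = 50.0  # depth band above the epithelium used for transport


@dataclass
class LayerDepths:
    asl_depth: float  # um (nan if unmeasurable)
    pcl_depth: float  # um
    epithelial_row: int
    mucus_surface_row: int | None
    cilia_tip_row: int | None
    flags: dict = field(default_factory=dict)


@dataclass
class CBFEstimate:
    cbf: float  # Hz (nan if unmeasurable)
    frequencies: np.ndarray
    power: np.ndarray
    resolution: float  # Hz
    measurable: bool
    snr: float


@dataclass
class Kymograph:
    matrix: np.ndarray  # (time, lateral)
    dt: float  # s per row
    dx: float  # um per column
    band_rows: tuple[int, int]

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dt and dx must be positive")


@dataclass
class MCTEstimate:
    mct_rate: float  # um/s, signed (nan if unmeasurable)
    confidence: float
    measurable: bool


@dataclass
class FunctionalMetrics:
    asl_depth: float
    pcl_depth: float
    cbf: float
    mct_rate: float
    roi_id: str = ""
    flags: dict = field(default_factory=dict)

    @property
    def mucus_depth(self) -> float:
        return self.asl_depth - self.pcl_depth


def measure_layer_depths(
    stack: ImageStack,
    variance_fraction: float = 0.3,
    intensity_fraction: float = 0.12,
    background_rows: int = 5,
) -> LayerDepths:
    """Locate the epithelial surface and the two liquid interfaces.

    On the time-averaged B-scan the epithelial surface is the
    maximum-intensity row.  The cilia-tip interface is the shallowest row
    whose laterally averaged reflectance has temporal variance above
    ``variance_fraction`` of the peak variance above the surface (coherent
    ciliary beating survives lateral averaging; sparse advected particulates
    do not, since their summed intensity per row is nearly constant); the
    air-mucus interface is the shallowest row whose mean intensity exceeds
    background by ``intensity_fraction`` of the surface contrast.  Metrics
    whose thresholds select nothing are flagged, never fabricated.
    """
    frames = stack.frames
    if frames.shape[0] < 1:
        raise ValueError("stack must contain at least one frame")
    ps = stack.pixel_size
    mean_img = frames.mean(axis=0)
    profile = mean_img.mean(axis=1)  # per-row mean intensity
    epi_row = int(np.argmax(profile))
    flags: dict = {}

    # temporal variance of the laterally averaged reflectance per row
    if frames.shape[0] > 1 and epi_row > 0:
        var_profile = frames.mean(axis=2).var(axis=0)[:epi_row]
        peak = var_profile.max()
        cilia_tip = None
        if peak > 0:
            above = np.flatnonzero(var_profile > variance_fraction * peak)
            if len(above):
                cilia_tip = int(above[0])
        if cilia_tip is None:
            flags["pcl"] = "no row passes the variance threshold"
            pcl_depth = np.nan
        else:
            pcl_depth = (epi_row - cilia_tip) * ps
    else:
        cilia_tip = None
        flags["pcl"] = "single frame: temporal variance undefined"
        pcl_depth = np.nan

    background = profile[: min(background_rows, epi_row)].mean() if epi_row else 0.0
    thresh = background + intensity_fraction * (profile[epi_row] - background)
    above = np.flatnonzero(profile[:epi_row] > thresh)
    if len(above):
        mucus_surface = int(above[0])
        asl_depth = (epi_row - mucus_surface) * ps
    else:
        mucus_surface = None
        flags["asl"] = "no row passes the intensity threshold"
        asl_depth = np.nan

    return LayerDepths(
        asl_depth=asl_depth,
        pcl_depth=pcl_depth,
        epithelial_row=epi_row,
        mucus_surface_row=mucus_surface,
        cilia_tip_row=cilia_tip,
        flags=flags,
    )


def estimate_cbf(
    stack: ImageStack,
    band: tuple[int, int] | None = None,
    search_band: tuple[float, float] = (2.0, 30.0),
    snr_threshold: float = 3.0,
) -> CBFEstimate:
    """Ciliary beat frequency from the averaged reflectance periodogram.

    Pixel time series inside ``band`` (row window; defaults to the detected
    PCL) are mean-detrended, Hann-windowed and their periodograms averaged;
    the CBF is the frequency of maximum averaged power inside
    ``search_band``.  The estimate is flagged unmeasurable when the peak
    does not exceed ``snr_threshold`` times the median in-band power.
    """
    frames = stack.frames
    n = frames.shape[0]
    if n < 256:
        raise ValueError("need at least 256 frames for a stable spectrum")
    if band is None:
        depths = measure_layer_depths(stack)
        if depths.cilia_tip_row is None:
            band = (max(0, depths.epithelial_row - 10), depths.epithelial_row)
        else:
            band = (depths.cilia_tip_row, depths.epithelial_row)
    r0, r1 = band
    sig = frames[:, r0:r1, :].reshape(n, -1).astype(float)
    sig = sig - sig.mean(axis=0, keepdims=True)
    window = np.hanning(n)[:, None]
    spec = np.abs(np.fft.rfft(sig * window, axis=0)) ** 2
    power = spec.mean(axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / stack.frame_rate)
    resolution = stack.frame_rate / n

    lo, hi = search_band
    hi = min(hi, stack.frame_rate / 2)
    mask = (freqs >= lo) & (freqs <= hi)
    in_band = power[mask]
    if not mask.any() or in_band.max() <= 0:
        return CBFEstimate(np.nan, freqs, power, resolution, False, 0.0)
    med = np.median(in_band)
    snr = float(in_band.max() / med) if med > 0 else np.inf
    measurable = snr >= snr_threshold and np.isfinite(snr) or (med == 0 and in_band.max() > 0)
    if not measurable:
        return CBFEstimate(np.nan, freqs, power, resolution, False, snr)
    cbf = float(freqs[mask][np.argmax(in_band)])
    return CBFEstimate(cbf, freqs, power, resolution, True, snr)


def build_kymograph(
    stack: ImageStack,
    epithelial_row: int,
    band_um: float = KYMO_BAND_UM,
) -> Kymograph:
    """Max-project the depth band above the epithelium onto the lateral axis,
    one row per frame."""
    band_px = int(round(band_um / stack.pixel_size))
    r0 = epithelial_row - band_px
    if epithelial_row <= 0 or epithelial_row > stack.frames.shape[1]:
        raise ValueError("epithelial_row outside the image")
    r0 = max(0, r0)
    if r0 >= epithelial_row:
        raise ValueError("depth band is empty")
    matrix = stack.frames[:, r0:epithelial_row, :].max(axis=1)
    return Kymograph(
        matrix=matrix,
        dt=1.0 / stack.frame_rate,
        dx=stack.pixel_size,
        band_rows=(r0, epithelial_row),
    )


def _shear_variance(matrix: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    """Variance of the time-stacked lateral profile after shearing each row
    by ``slope * t`` columns (wrapped linear interpolation)."""
    t_idx = np.arange(matrix.shape[0])[:, None]
    x_idx = np.arange(matrix.shape[1])[None, :]
    rows = np.arange(matrix.shape[0])[:, None]
    out = np.empty(len(slopes))
    w = matrix.shape[1]
    for i, s in enumerate(slopes):
        pos = (x_idx + s * t_idx) % w
        i0 = np.floor(pos).astype(int)
        frac = pos - i0
        i1 = (i0 + 1) % w
        vals = matrix[rows, i0] * (1 - frac) + matrix[rows, i1] * frac
        out[i] = vals.mean(axis=0).var()
    return out


def estimate_mct_rate(
    kymo: Kymograph,
    max_angle_deg: float = 80.0,
    step_deg: float = 0.2,
    confidence_threshold: float = 2.0,
) -> MCTEstimate:
    """Transport rate from the dominant streak orientation of a kymograph.

    The streak slope is found by maximizing the variance of the
    shear-and-stack lateral profile over a grid of angles (step
    ``step_deg``), refined by parabolic interpolation of the variance peak;
    ``rate = tan(angle) * dx / dt``.  Confidence is the peak-to-median
    variance ratio over the angle grid; an isotropic kymograph is flagged
    unmeasurable.
    """
    m = kymo.matrix
    if m.shape[0] < 10:
        raise ValueError("kymograph needs at least 10 rows")
    work = m - np.median(m)
    n_steps = int(round(max_angle_deg / step_deg))
    angles = np.linspace(-max_angle_deg, max_angle_deg, 2 * n_steps + 1)
    slopes = np.tan(np.deg2rad(angles))
    scores = _shear_variance(work, slopes)
    med = np.median(scores)
    peak = scores.max()
    confidence = float(peak / med) if med > 0 else np.inf
    if not np.isfinite(confidence) or confidence < confidence_threshold or peak <= 0:
        return MCTEstimate(np.nan, confidence if np.isfinite(confidence) else 0.0, False)
    k = int(np.argmax(scores))
    best = angles[k]
    if 0 < k < len(angles) - 1:  # parabolic sub-grid refinement
        y0, y1, y2 = scores[k - 1], scores[k], scores[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            best = best + 0.5 * (y0 - y2) / denom * step_deg
    rate = float(np.tan(np.deg2rad(best)) * kymo.dx / kymo.dt)
    return MCTEstimate(rate, confidence, True)


def analyze_stack(stack: ImageStack, roi_id: str = "") -> FunctionalMetrics:
    """Run all four estimators on one stack."""
    depths = measure_layer_depths(stack)
    cbf = estimate_cbf(stack)
    flags = dict(depths.flags)
    if not cbf.measurable:
        flags["cbf"] = "spectral peak below SNR threshold"
    kymo = build_kymograph(stack, depths.epithelial_row)
    mct = estimate_mct_rate(kymo)
    if not mct.measurable:
        flags["mct"] = "kymograph isotropic"
    return FunctionalMetrics(
        asl_depth=depths.asl_depth,
        pcl_depth=depths.pcl_depth,
        cbf=cbf.cbf,
        mct_rate=mct.mct_rate,
        roi_id=roi_id,
        flags=flags,
    )
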