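"""Seeded synthetic-data generators for every pipeline input.

Each generator returns the synthetic object together with (or carrying) the
:class:`GroundTruth` that produced it, so downstream estimators can always
be checked against known truth.  All randomness flows through
``numpy.random.default_rng(seed)``; identical seeds give bit-identical
output.

Conventions: images are (time, row, column) with the top-left origin and
depth increasing downward; positions are micrometres unless a name says
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .microrheology import Trajectory, TrajectorySet

__all__ = [
    "GroundTruth",
    "ImageStack",
    "PlateData",
    "LavageCounts",
    "SurvivalTable",
    "SHGFieldSet",
    "simulate_trajectories",
    "render_bead_movie",
    "simulate_muoct_stack",
    "simulate_shg_field_set",
    "simulate_plate_assay",
    "simulate_lavage_experiment",
    "sample_fields_uniform",
]


@dataclass
class GroundTruth:
    """Hidden parameters of a synthetic dataset.

    Only the fields relevant to a given generator are populated; the rest
    stay ``None``.  Recovery tests compare estimates against these values.
    """

    diffusion_coeff: float | None = None  # um^2/s
    anomalous_exponent: float | None = None  # (0, 2]
    drift_velocity: tuple[float, float] | None = None  # um/s
    localization_sigma: float | None = None  # um
    asl_depth: float | None = None  # um
    pcl_depth: float | None = None  # um
    cbf: float | None = None  # Hz
    mct_rate: float | None = None  # um/s
    collagen_fraction: float | None = None  # percent
    curve_slope: float | None = None
    curve_intercept: float | None = None
    group_means: tuple | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anomalous_exponent is not None and not (
            0 < self.anomalous_exponent <= 2
        ):
            raise ValueError("anomalous_exponent must be in (0, 2]")
        if self.collagen_fraction is not None and not (
            0 <= self.collagen_fraction <= 100
        ):
            raise ValueError("collagen_fraction must be in [0, 100]")
        for name in ("diffusion_coeff", "localization_sigma", "asl_depth",
                     "pcl_depth", "cbf"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if v is None or k == "extra":
                continue
            d[k] = list(v) if isinstance(v, tuple) else v
        d.update(self.extra)
        return d


@dataclass
class ImageStack:
    """Multi-frame grayscale image stack with physical calibration."""

    frames: np.ndarray  # (time, row, column)
    pixel_size: float  # um / pixel
    frame_rate: float  # frames / s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (time, row, column)")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")
        if not np.isfinite(self.frames).all():
            raise ValueError("intensities must be finite")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def truth(self) -> GroundTruth | None:
        return self.metadata.get("truth")


@dataclass
class PlateData:
    """Colorimetric plate layout: standards plus unknowns, with truth."""

    wells: pd.DataFrame  # columns: role, sample_id, concentration, replicate, absorbance
    truth: GroundTruth


@dataclass
class LavageCounts:
    counts: pd.DataFrame  # columns: group, animal, total_cells
    truth: GroundTruth


@dataclass
class SurvivalTable:
    groups: list[str]
    deaths: list[int]
    totals: list[int]


@dataclass
class SHGFieldSet:
    fields: list[np.ndarray]  # rendered intensity images
    masks: list[np.ndarray]  # boolean truth masks
    truth: GroundTruth

    @property
    def true_fractions(self) -> np.ndarray:
        return np.array([100.0 * m.mean() for m in self.masks])


# ---------------------------------------------------------------------------
# bead trajectories
# ---------------------------------------------------------------------------


def _fgn_increments(
    rng: np.random.Generator, n_steps: int, n_series: int, hurst: float
) -> np.ndarray:
    """Unit-variance fractional Gaussian noise via Cholesky of the
    autocovariance (exact; fine at fixture sizes)."""
    k = np.arange(n_steps)
    h2 = 2.0 * hurst
    gamma = 0.5 * (
        np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2
    )
    cov = gamma[np.abs(k[:, None] - k[None, :])]
    # tiny jitter guards against numerically semi-definite matrices near H=1
    cov[np.diag_indices_from(cov)] += 1e-12
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_steps, n_series))
    return (chol @ z).T  # (n_series, n_steps)


def simulate_trajectories(
    n_beads: int,
    n_frames: int,
    dt: float,
    diffusion_coeff: float,
    anomalous_exponent: float = 1.0,
    drift_velocity: Sequence[float] = (0.0, 0.0),
    localization_sigma: float = 0.0,
    seed: int | None = None,
    initial_positions: np.ndarray | None = None,
) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate 2-D bead tracks: (sub/super)diffusion + drift + noise.

    With ``anomalous_exponent == 1`` increments are plain Brownian with
    per-axis variance ``2 * D * dt``; otherwise fractional Gaussian noise
    with Hurst index ``alpha / 2`` is used, normalized so the per-axis MSD
    is ``2 * D * t**alpha``.  Drift adds ``v * dt`` per frame and
    localization noise adds i.i.d. Gaussian jitter to each observed
    coordinate.

    ``initial_positions`` (n_beads, 2) places beads for rendering; defaults
    to the origin for every bead.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (0 < anomalous_exponent <= 2):
        raise ValueError("anomalous_exponent must be in (0, 2]")
    if diffusion_coeff < 0 or localization_sigma < 0:
        raise ValueError("diffusion_coeff and localization_sigma must be >= 0")
    if seed is None:
        raise ValueError("seed must be supplied")

    rng = np.random.default_rng(seed)
    n_steps = n_frames - 1
    alpha = anomalous_exponent
    sigma_step = np.sqrt(2.0 * diffusion_coeff * dt**alpha)

    if diffusion_coeff == 0:
        inc = np.zeros((n_beads, 2, n_steps))
    elif alpha == 1.0:
        inc = rng.standard_normal((n_beads, 2, n_steps)) * sigma_step
    elif alpha == 2.0:
        # ballistic limit: perfectly correlated increments (random velocity)
        v = rng.standard_normal((n_beads, 2, 1)) * sigma_step
        inc = np.repeat(v, n_steps, axis=2)
    else:
        flat = _fgn_increments(rng, n_steps, n_beads * 2, hurst=alpha / 2.0)
        inc = flat.reshape(n_beads, 2, n_steps) * sigma_step

    times = np.arange(n_frames) * dt
    v = np.asarray(drift_velocity, dtype=float)
    drift = np.outer(times, v)  # (n_frames, 2)
    if initial_positions is None:
        initial_positions = np.zeros((n_beads, 2))
    else:
        initial_positions = np.asarray(initial_positions, dtype=float)
        if initial_positions.shape != (n_beads, 2):
            raise ValueError("initial_positions must have shape (n_beads, 2)")

    noise = (
        rng.standard_normal((n_beads, n_frames, 2)) * localization_sigma
        if localization_sigma > 0
        else np.zeros((n_beads, n_frames, 2))
    )

    trajs = []
    for b in range(n_beads):
        pos = np.zeros((n_frames, 2))
        pos[1:] = np.cumsum(inc[b].T, axis=0)
        pos += initial_positions[b] + drift + noise[b]
        trajs.append(Trajectory(bead_id=b, times=times, x=pos[:, 0], y=pos[:, 1]))

    truth = GroundTruth(
        diffusion_coeff=diffusion_coeff,
        anomalous_exponent=alpha,
        drift_velocity=tuple(v),
        localization_sigma=localization_sigma,
        seed=seed,
    )
    ts = TrajectorySet(trajs, metadata={"dt": dt, "truth": truth})
    return ts, truth


def render_bead_movie(
    trajectories: TrajectorySet,
    image_shape: tuple[int, int],
    psf_sigma: float = 1.5,
    peak_intensity: float = 100.0,
    background_noise_sigma: float = 0.0,
    pixel_size: float = 0.1,
    seed: int | None = 0,
) -> ImageStack:
    """Render trajectories to a movie of Gaussian spots plus noise.

    Every trajectory position must fall inside the frame after um -> pixel
    conversion; a position outside raises with the offending bead and frame.
    """
    h, w = image_shape
    trajs = list(trajectories)
    n_frames = max(t.n_frames for t in trajs)
    dt = trajs[0].dt
    rng = np.random.default_rng(seed)

    # precheck all positions
    for t in trajs:
        col = t.x / pixel_size
        row = t.y / pixel_size
        bad = np.where((col < 0) | (col > w - 1) | (row < 0) | (row > h - 1))[0]
        if len(bad):
            raise ValueError(
                f"bead {t.bead_id} leaves the frame at frame {int(bad[0])}"
            )

    win = int(np.ceil(4 * psf_sigma))
    # float32 frames with per-frame noise keep memory flat for long movies
    frames = np.zeros((n_frames, h, w), dtype=np.float32)
    for t in trajs:
        cols = t.x / pixel_size
        rows = t.y / pixel_size
        for fi in range(t.n_frames):
            r, c = rows[fi], cols[fi]
            r0, r1 = max(0, int(r) - win), min(h, int(r) + win + 1)
            c0, c1 = max(0, int(c) - win), min(w, int(c) + win + 1)
            rr = np.arange(r0, r1)[:, None]
            cc = np.arange(c0, c1)[None, :]
            frames[fi, r0:r1, c0:c1] += peak_intensity * np.exp(
                -((rr - r) ** 2 + (cc - c) ** 2) / (2 * psf_sigma**2)
            )
    if background_noise_sigma > 0:
        for fi in range(n_frames):
            frames[fi] += rng.normal(0, background_noise_sigma, (h, w)).astype(np.float32)
        np.clip(frames, 0, None, out=frames)

    meta = {
        "seed": seed,
        "psf_sigma": psf_sigma,
        "peak_intensity": peak_intensity,
        "source_trajectories": trajectories,
        "truth": trajectories.metadata.get("truth"),
    }
    return ImageStack(frames, pixel_size=pixel_size, frame_rate=1.0 / dt, metadata=meta)


# ---------------------------------------------------------------------------
# muOCT phantom
# ---------------------------------------------------------------------------

_AIR_I = 0.02
_MUCUS_I = 0.25
_PCL_BASE_I = 0.30
_PCL_AMP_I = 0.22
_EPI_I = 1.0
_PARTICLE_I = 0.9


def simulate_muoct_stack(
    asl_depth: float,
    pcl_depth: float,
    cbf: float,
    mct_rate: float,
    frame_rate: float = 100.0,
    n_frames: int = 400,
    lines_per_frame: int = 256,
    pixel_size: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Phantom B-scan time series for the functional-metric estimators.

    From the bottom up: a bright epithelial surface row, a periciliary band
    of thickness ``pcl_depth`` whose reflectance oscillates sinusoidally at
    ``cbf``, and a mucus layer filling the airway surface liquid to
    ``asl_depth``; bright particulates in the mucus advect laterally at
    ``mct_rate`` (wrapping at the edges).  Speckle is approximated by
    additive Gaussian noise.
    """
    if asl_depth < pcl_depth or pcl_depth < 0:
        raise ValueError("need asl_depth >= pcl_depth >= 0")
    if cbf >= frame_rate / 2:
        raise ValueError(
            f"cbf={cbf} Hz is not resolvable at frame_rate={frame_rate} "
            "(Nyquist violation)"
        )
    rng = np.random.default_rng(seed)

    asl_px = int(round(asl_depth / pixel_size))
    pcl_px = int(round(pcl_depth / pixel_size))
    air_px = 20
    epi_row = air_px + asl_px
    depth_px = epi_row + 8
    w = lines_per_frame

    t = np.arange(n_frames) / frame_rate
    frames = np.full((n_frames, depth_px, w), _AIR_I, dtype=np.float64)

    mucus_top = epi_row - asl_px
    pcl_top = epi_row - pcl_px
    frames[:, mucus_top:pcl_top, :] = _MUCUS_I
    if pcl_px > 0:
        osc = _PCL_BASE_I + _PCL_AMP_I * np.sin(2 * np.pi * cbf * t)
        frames[:, pcl_top:epi_row, :] = osc[:, None, None]
    frames[:, epi_row, :] = _EPI_I
    frames[:, epi_row + 1 :, :] = 0.15

    # advected particulates in the mucus band (<= 50 um above the surface)
    band_top = max(mucus_top, epi_row - int(round(50.0 / pixel_size)))
    band_bot = pcl_top  # keep the PCL variance signature clean
    if band_bot - band_top >= 3 and asl_px > pcl_px:
        n_part = max(3, w // 40)
        rows = rng.integers(band_top + 1, band_bot - 1, n_part)
        x0 = rng.uniform(0, w, n_part)
        px_per_frame = mct_rate / pixel_size / frame_rate
        xs = np.arange(w)
        for p in range(n_part):
            centers = (x0[p] + px_per_frame * np.arange(n_frames)) % w
            # wrapped lateral Gaussian profile, 1.2 px wide
            d = np.abs(xs[None, :] - centers[:, None])
            d = np.minimum(d, w - d)
            prof = _PARTICLE_I * np.exp(-(d**2) / (2 * 1.2**2))
            for dr in (-1, 0, 1):
                r = rows[p] + dr
                fac = 1.0 if dr == 0 else 0.5
                frames[:, r, :] = np.maximum(frames[:, r, :], fac * prof)

    if noise_sigma > 0:
        frames += rng.normal(0, noise_sigma, frames.shape)
        np.clip(frames, 0, None, out=frames)

    truth = GroundTruth(
        asl_depth=asl_depth,
        pcl_depth=pcl_depth,
        cbf=cbf,
        mct_rate=mct_rate,
        seed=seed,
        extra={"epithelial_row": epi_row},
    )
    stack = ImageStack(
        frames,
        pixel_size=pixel_size,
        frame_rate=frame_rate,
        metadata={"seed": seed, "truth": truth, "epithelial_row": epi_row},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# SHG fields
# ---------------------------------------------------------------------------


def _draw_segment(mask: np.ndarray, rng: np.random.Generator,
                  length: float, width: float) -> None:
    """Rasterize one randomly placed, randomly oriented thick segment."""
    h, w = mask.shape
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    theta = rng.uniform(0, np.pi)
    dy, dx = np.sin(theta), np.cos(theta)
    n = max(2, int(np.ceil(length)))
    s = np.linspace(-length / 2, length / 2, n)
    ys = np.clip(np.round(cy + s * dy).astype(int), 0, h - 1)
    xs = np.clip(np.round(cx + s * dx).astype(int), 0, w - 1)
    r = max(0, int(round((width - 1) / 2)))
    for oy in range(-r, r + 1):
        for ox in range(-r, r + 1):
            mask[np.clip(ys + oy, 0, h - 1), np.clip(xs + ox, 0, w - 1)] = True


def simulate_shg_field_set(
    n_fields: int,
    collagen_fraction: float,
    fiber_count: int = 30,
    fiber_width: float = 3.0,
    image_shape: tuple[int, int] = (128, 128),
    between_field_sd: float = 0.0,
    noise_sigma: float = 0.0,
    blur_sigma: float = 0.0,
    seed: int | None = 0,
) -> tuple[SHGFieldSet, GroundTruth]:
    """Fields of random fibrillar segments at a controlled area fraction.

    The per-field target fraction is drawn around ``collagen_fraction`` with
    spread ``between_field_sd``; segments are added until the mask reaches
    the target, then the pixel count is trimmed to match it exactly, so the
    truth-mask fraction equals the per-field target to rounding.
    """
    if not 0 <= collagen_fraction <= 100:
        raise ValueError("collagen_fraction must be in [0, 100]")
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if fiber_count < 1 or fiber_width < 1:
        raise ValueError("fiber geometry infeasible")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    npix = h * w

    fields, masks = [], []
    for _ in range(n_fields):
        target = collagen_fraction
        if between_field_sd > 0:
            target = float(np.clip(rng.normal(collagen_fraction, between_field_sd), 0, 100))
        target_px = int(round(target / 100.0 * npix))
        mask = np.zeros((h, w), dtype=bool)
        if target_px >= npix:
            mask[:] = True
        elif target_px > 0:
            seg_len = max(4.0, target_px / (fiber_count * fiber_width))
            guard = 0
            while mask.sum() < target_px and guard < 50 * fiber_count:
                _draw_segment(mask, rng, seg_len, fiber_width)
                guard += 1
            excess = int(mask.sum()) - target_px
            if excess > 0:  # trim random foreground pixels to the exact count
                fg = np.flatnonzero(mask)
                off = rng.choice(fg, size=excess, replace=False)
                mask.flat[off] = False
        img = mask.astype(float)
        if blur_sigma > 0:
            from scipy.ndimage import gaussian_filter

            img = gaussian_filter(img, blur_sigma)
        if noise_sigma > 0:
            img = img + rng.normal(0, noise_sigma, img.shape)
            np.clip(img, 0, None, out=img)
        fields.append(img)
        masks.append(mask)

    truth = GroundTruth(collagen_fraction=collagen_fraction, seed=seed,
                        extra={"between_field_sd": between_field_sd})
    return SHGFieldSet(fields=fields, masks=masks, truth=truth), truth


# ---------------------------------------------------------------------------
# plate assays, lavage counts, sampling
# ---------------------------------------------------------------------------


def simulate_plate_assay(
    true_concentrations: Sequence[float],
    curve_slope: float,
    curve_intercept: float,
    replicate_cv: float = 0.0,
    n_replicates: int = 2,
    standard_concentrations: Sequence[float] | None = None,
    seed: int | None = 0,
) -> PlateData:
    """Linear colorimetric plate with multiplicative well noise.

    Absorbance is ``intercept + slope * conc`` times ``1 + cv * N(0, 1)``.
    Standards (default: 6 levels spanning the unknowns) and unknowns are
    plated with the same replicate count.
    """
    conc = np.asarray(true_concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if replicate_cv < 0:
        raise ValueError("replicate_cv must be >= 0")
    rng = np.random.default_rng(seed)

    if standard_concentrations is None:
        top = max(conc.max() * 1.5, 1.0) if conc.size else 1.0
        standard_concentrations = np.linspace(0, top, 6)
    stds = np.asarray(standard_concentrations, dtype=float)

    rows = []
    for role, cs in (("standard", stds), ("unknown", conc)):
        for si, c in enumerate(cs):
            clean = curve_intercept + curve_slope * c
            for rep in range(n_replicates):
                a = clean
                if replicate_cv > 0:
                    a = clean * (1.0 + replicate_cv * rng.standard_normal())
                rows.append((role, f"{role[0]}{si}", c, rep, a))
    wells = pd.DataFrame(
        rows, columns=["role", "sample_id", "concentration", "replicate", "absorbance"]
    )
    truth = GroundTruth(curve_slope=curve_slope, curve_intercept=curve_intercept,
                        seed=seed, extra={"replicate_cv": replicate_cv})
    return PlateData(wells=wells, truth=truth)


def simulate_lavage_experiment(
    group_sizes: Sequence[int],
    group_means: Sequence[float],
    dispersion: float = 5.0,
    deaths_per_group: Sequence[int] | None = None,
    poisson: bool = False,
    group_names: Sequence[str] | None = None,
    seed: int | None = 0,
) -> tuple[LavageCounts, SurvivalTable]:
    """Overdispersed leukocyte counts plus a per-group survival table.

    Counts are negative-binomial with ``var = mean + mean**2 / dispersion``;
    pass ``poisson=True`` for the equidispersed limit.
    """
    sizes = [int(s) for s in group_sizes]
    means = [float(m) for m in group_means]
    if len(sizes) != len(means):
        raise ValueError("group_sizes and group_means must align")
    if any(s < 1 for s in sizes):
        raise ValueError("all group sizes must be >= 1")
    if not poisson and dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if deaths_per_group is None:
        deaths_per_group = [0] * len(sizes)
    if any(d > s for d, s in zip(deaths_per_group, sizes)):
        raise ValueError("deaths cannot exceed group size")
    if group_names is None:
        group_names = [f"group{i}" for i in range(len(sizes))]
    rng = np.random.default_rng(seed)

    rows = []
    for g, (name, size, mean) in enumerate(zip(group_names, sizes, means)):
        if poisson:
            counts = rng.poisson(mean, size)
        else:
            p = dispersion / (dispersion + mean)
            counts = rng.negative_binomial(dispersion, p, size)
        for a, c in enumerate(counts):
            rows.append((name, a, int(c)))
    df = pd.DataFrame(rows, columns=["group", "animal", "total_cells"])
    truth = GroundTruth(group_means=tuple(means), seed=seed,
                        extra={"dispersion": None if poisson else dispersion})
    surv = SurvivalTable(groups=list(group_names),
                         deaths=[int(d) for d in deaths_per_group],
                         totals=sizes)
    return LavageCounts(counts=df, truth=truth), surv


def sample_fields_uniform(
    grid_shape: tuple[int, int],
    n_fields: int,
    seed: int | None = 0,
) -> list[tuple[int, int]]:
    """Systematic uniform random sampling of grid positions.

    A random fractional start and fixed stride ``total / n_fields`` over the
    flattened grid; every position has inclusion probability exactly
    ``n_fields / total`` and no position repeats.
    """
    rows, cols = grid_shape
    total = rows * cols
    if n_fields > total:
        raise ValueError(f"n_fields={n_fields} exceeds grid size {total}")
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    rng = np.random.default_rng(seed)
    stride = total / n_fields
    start = rng.uniform(0, stride)
    flat = np.floor(start + stride * np.arange(n_fields)).astype(int)
    return [(int(f) // cols, int(f) % cols) for f in flat]
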