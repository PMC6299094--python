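"""Configuration-driven end-to-end synthetic study.

``run_study`` generates a full synthetic dataset (bead movies, B-scan
phantoms, SHG fields, plates, lavage counts), runs every analysis stage on
it and writes a consolidated JSON report with truth-versus-estimate rows
and all group tests.  A single master seed is fanned out deterministically
to per-stage child seeds via ``numpy.random.SeedSequence.spawn``, so reruns
with the same config are bit-identical and stages are independently
reproducible.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np

from . import assays, microrheology as mrh, muoct, shg, synthetic

__all__ = ["DEFAULT_CONFIG", "load_config", "run_study"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "microrheology": {
        "n_beads": 40,
        "n_frames": 300,
        "dt": 1.0 / 60.0,
        "diffusion_coeff": 0.25,  # um^2/s
        "anomalous_exponent": 1.0,
        "drift_velocity": [0.5, -0.3],  # um/s
        "pixel_size": 0.2,  # um/px
        "image_size": 192,
        "psf_sigma": 1.3,
        "peak_intensity": 100.0,
        "background_noise_sigma": 2.0,
        "intensity_percentile": 99.5,
        "fit_lags": [2, 20],
        "d_tolerance": 0.15,
        "alpha_tolerance": 0.1,
    },
    "muoct": {
        "n_animals_per_group": 4,
        "rois_per_animal": 2,
        "n_frames": 300,
        "frame_rate": 100.0,
        "lines_per_frame": 160,
        "pixel_size": 1.0,
        "noise_sigma": 0.02,
        "groups": {
            "WT": {"asl_depth": 15.0, "pcl_depth": 7.0, "cbf": 12.0, "mct_rate": 45.0},
            "Tg": {"asl_depth": 30.0, "pcl_depth": 7.0, "cbf": 8.0, "mct_rate": 15.0},
        },
    },
    "shg": {
        "n_animals_per_group": 3,
        "fields_per_animal": 10,
        "image_shape": [64, 64],
        "between_field_sd": 2.0,
        "noise_sigma": 0.05,
        "groups": {"control": 8.0, "treated": 25.0},  # percent area
        "alpha": 0.001,
        "max_peaks": 3,
    },
    "assays": {
        "curve_slope": 0.02,
        "curve_intercept": 0.05,
        "replicate_cv": 0.03,
        "unknown_concentrations": [5.0, 10.0, 20.0],
        "dtnb": {"k_fast": 0.05, "k_slow": 0.02, "noise": 0.01, "n_points": 60},
        "lavage": {
            "vehicle_mean": 120.0,
            "treated_mean": 70.0,
            "n_vehicle": 12,
            "n_treated": 13,
            "dispersion": 5.0,
        },
        "survival": [[10, 20], [2, 20]],  # (deaths, total) per group
        "sweep": {"plateau_pa": 2.5, "frequency": 1.0},
        "viscosity_mass": {"slope": 0.5, "intercept": 1.0},
    },
    "null_effect": False,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Default config merged with an optional YAML/JSON file and overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(master).spawn(n)]


def _relerr(est: float, truth: float) -> float:
    return abs(est - truth) / abs(truth) if truth else abs(est)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_microrheology(cfg: dict, seed: int) -> dict:
    c = cfg["microrheology"]
    size, margin = c["image_size"], 30
    n = c["n_beads"]
    side = int(np.ceil(np.sqrt(n)))
    span = (size - 2 * margin) * c["pixel_size"]
    gx, gy = np.meshgrid(np.linspace(0, span, side), np.linspace(0, span, side))
    init = np.column_stack([gx.ravel()[:n], gy.ravel()[:n]]) + margin * c["pixel_size"]

    ts, truth = synthetic.simulate_trajectories(
        n_beads=n, n_frames=c["n_frames"], dt=c["dt"],
        diffusion_coeff=c["diffusion_coeff"],
        anomalous_exponent=c["anomalous_exponent"],
        drift_velocity=(0.0, 0.0),  # drift injected below so rendering stays in frame
        localization_sigma=0.0, seed=seed, initial_positions=init,
    )
    movie = synthetic.render_bead_movie(
        ts, (size, size), psf_sigma=c["psf_sigma"],
        peak_intensity=c["peak_intensity"],
        background_noise_sigma=c["background_noise_sigma"],
        pixel_size=c["pixel_size"], seed=seed + 1,
    )
    linked = mrh.detect_and_link(
        movie, expected_diameter=7,
        intensity_percentile=c["intensity_percentile"],
        max_displacement=4.0, min_length=c["n_frames"] // 2,
    )
    corrected, drift = mrh.correct_linear_drift(linked)
    curve = mrh.ensemble_msd(corrected, max_lag=c["fit_lags"][1] + 5)
    alpha_hat, d_hat = mrh.fit_scaling(curve, tuple(c["fit_lags"]))
    return {
        "truth": {"diffusion_coeff": c["diffusion_coeff"],
                  "anomalous_exponent": c["anomalous_exponent"]},
        "estimate": {"diffusion_coeff": d_hat, "anomalous_exponent": alpha_hat,
                     "n_trajectories": len(corrected),
                     "drift_um_per_s": drift.tolist()},
        "recovered": bool(
            _relerr(d_hat, c["diffusion_coeff"]) < c["d_tolerance"]
            and abs(alpha_hat - c["anomalous_exponent"]) < c["alpha_tolerance"]
        ),
    }


def _stage_muoct(cfg: dict, seed: int) -> dict:
    c = cfg["muoct"]
    rng = np.random.default_rng(seed)
    groups = copy.deepcopy(c["groups"])
    if cfg.get("null_effect"):
        first = next(iter(groups.values()))
        groups = {k: dict(first) for k in groups}
    per_metric: dict[str, dict[str, list[float]]] = {
        m: {g: [] for g in groups} for m in ("mucus_depth", "pcl_depth", "cbf", "mct_rate")
    }
    rows = []
    for gname, truthc in groups.items():
        for a in range(c["n_animals_per_group"]):
            roi_vals = {m: [] for m in per_metric}
            for r in range(c["rois_per_animal"]):
                jit = rng.normal(0, 0.03, 4)  # mild between-ROI variation
                stack, _ = synthetic.simulate_muoct_stack(
                    asl_depth=truthc["asl_depth"] * (1 + jit[0]),
                    pcl_depth=truthc["pcl_depth"] * (1 + 0.3 * jit[1]),
                    cbf=truthc["cbf"] * (1 + 0.2 * jit[2]),
                    mct_rate=truthc["mct_rate"] * (1 + jit[3]),
                    frame_rate=c["frame_rate"], n_frames=c["n_frames"],
                    lines_per_frame=c["lines_per_frame"],
                    pixel_size=c["pixel_size"], noise_sigma=c["noise_sigma"],
                    seed=int(rng.integers(0, 2**31)),
                )
                fm = muoct.analyze_stack(stack, roi_id=f"{gname}-{a}-{r}")
                roi_vals["mucus_depth"].append(fm.mucus_depth)
                roi_vals["pcl_depth"].append(fm.pcl_depth)
                roi_vals["cbf"].append(fm.cbf)
                roi_vals["mct_rate"].append(fm.mct_rate)
            animal_means = {m: float(np.nanmean(v)) for m, v in roi_vals.items()}
            rows.append({"group": gname, "animal": a, **animal_means})
            for m in per_metric:
                per_metric[m][gname].append(animal_means[m])
    tests = {}
    gnames = list(groups)
    for m, vals in per_metric.items():
        rep = assays.group_compare(
            {g: vals[g] for g in gnames}, method="mann_whitney"
        )
        tests[m] = {"p": rep["p"], "statistic": rep["statistic"]}
    return {"truth": groups, "animals": rows, "mann_whitney": tests}


def _stage_shg(cfg: dict, seed: int) -> dict:
    c = cfg["shg"]
    rng = np.random.default_rng(seed)
    groups = dict(c["groups"])
    if cfg.get("null_effect"):
        first = next(iter(groups.values()))
        groups = {k: first for k in groups}
    fractions: dict[str, list[float]] = {}
    for gname, frac in groups.items():
        vals = []
        for a in range(c["n_animals_per_group"]):
            fs, _ = synthetic.simulate_shg_field_set(
                n_fields=c["fields_per_animal"], collagen_fraction=frac,
                image_shape=tuple(c["image_shape"]),
                between_field_sd=c["between_field_sd"],
                noise_sigma=c["noise_sigma"],
                seed=int(rng.integers(0, 2**31)),
            )
            vals.extend(
                shg.collagen_area_fraction(f, threshold=0.5) for f in fs.fields
            )
        fractions[gname] = vals
    gnames = list(groups)
    fits = {
        g: shg.fit_gaussian_mixture_histogram(
            fractions[g], max_peaks=c["max_peaks"], bin_rule="fd"
        )
        for g in gnames
    }
    rr = shg.rejection_region_test(
        fractions[gnames[0]], fractions[gnames[1]], alpha=c["alpha"]
    )
    return {
        "truth": groups,
        "mean_fraction": {g: float(np.mean(fractions[g])) for g in gnames},
        "mixture": {
            g: {"n_peaks": f.n_peaks, "means": f.means.tolist(),
                "chi2": f.chi2, "dof": f.dof}
            for g, f in fits.items()
        },
        "rejection_region": {
            "t": rr.t_statistic, "df": rr.df,
            "critical_value": rr.critical_value, "significant": rr.decision,
        },
    }


def _stage_assays(cfg: dict, seed: int) -> dict:
    c = cfg["assays"]
    seeds = _child_seeds(seed, 5)
    out: dict = {}

    plate = synthetic.simulate_plate_assay(
        c["unknown_concentrations"], c["curve_slope"], c["curve_intercept"],
        replicate_cv=c["replicate_cv"], n_replicates=2, seed=seeds[0],
    )
    w = plate.wells
    stds = (
        w[w.role == "standard"].groupby("sample_id")
        .agg(conc=("concentration", "first"), a=("absorbance", "mean"))
    )
    unknown_groups = [
        grp["absorbance"].tolist()
        for _, grp in w[w.role == "unknown"].groupby("sample_id", sort=False)
    ]
    concs, curve, _ = assays.standard_curve_concentration(
        list(zip(stds.conc, stds.a)), unknown_groups
    )
    out["standard_curve"] = {
        "truth": list(c["unknown_concentrations"]),
        "estimate": concs.tolist(),
        "r_squared": curve.r_squared,
    }

    rng = np.random.default_rng(seeds[1])
    t = np.linspace(0, 120, c["dtnb"]["n_points"])
    fitted = {}
    for name, k in (("fast", c["dtnb"]["k_fast"]), ("slow", c["dtnb"]["k_slow"])):
        a = 0.05 + 0.8 * (1 - np.exp(-k * t))
        a = a + rng.normal(0, c["dtnb"]["noise"] * 0.8, a.shape)
        fitted[name] = assays.dtnb_rate(t, a)
    out["dtnb"] = {
        "truth_ratio": c["dtnb"]["k_fast"] / c["dtnb"]["k_slow"],
        "estimate_ratio": assays.rate_ratio(fitted["fast"], fitted["slow"]),
        "k": {n: f.rate_constant for n, f in fitted.items()},
    }

    lv = c["lavage"]
    treated_mean = lv["vehicle_mean"] if cfg.get("null_effect") else lv["treated_mean"]
    lav, surv = synthetic.simulate_lavage_experiment(
        [lv["n_vehicle"], lv["n_treated"]],
        [lv["vehicle_mean"], treated_mean],
        dispersion=lv["dispersion"],
        deaths_per_group=[d for d, _ in c["survival"]],
        group_names=["vehicle", "treated"], seed=seeds[2],
    )
    dfc = lav.counts
    aec = assays.acute_endogenous_clearance(
        dfc[dfc.group == "vehicle"].total_cells,
        dfc[dfc.group == "treated"].total_cells,
    )
    out["aec"] = aec

    chi2, df, p = assays.survival_chisq(c["survival"])
    out["survival"] = {"chi2": chi2, "df": df, "p": p}

    rng = np.random.default_rng(seeds[3])
    stress = np.logspace(-2, 1, 20)
    g0 = c["sweep"]["plateau_pa"]
    mod = np.where(stress < 1.0, g0, g0 * (stress / 1.0) ** -0.6)
    mod = mod * (1 + rng.normal(0, 0.02, mod.shape))
    eta, info = assays.linear_regime_viscosity(stress, mod, c["sweep"]["frequency"])
    out["viscosity"] = {
        "truth": g0 / c["sweep"]["frequency"], "estimate": eta, **info,
    }

    rng = np.random.default_rng(seeds[4])
    mass = np.linspace(2, 50, 8)
    visc = c["viscosity_mass"]["intercept"] + c["viscosity_mass"]["slope"] * mass
    visc = visc + rng.normal(0, 0.3, visc.shape)
    out["viscosity_mass"] = {
        "truth_slope": c["viscosity_mass"]["slope"],
        **assays.viscosity_mass_regression(list(zip(mass, visc))),
    }
    return out


def run_study(config: dict | None = None, outdir=None, seed: int | None = None) -> dict:
    """Execute all stages and (optionally) write the report bundle.

    ``seed`` overrides ``config['seed']``.  The report contains no
    timestamps, so identical configs produce byte-identical files.
    """
    cfg = _deep_merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    s_mrh, s_oct, s_shg, s_assay = _child_seeds(cfg["seed"], 4)

    report = {
        "config_seed": cfg["seed"],
        "null_effect": bool(cfg.get("null_effect")),
        "stages": {
            "microrheology": _stage_microrheology(cfg, s_mrh),
            "muoct": _stage_muoct(cfg, s_oct),
            "shg": _stage_shg(cfg, s_shg),
            "assays": _stage_assays(cfg, s_assay),
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float)
        )
        (outdir / "config.json").write_text(
            json.dumps(cfg, indent=2, sort_keys=True, default=float)
        )
    return report
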