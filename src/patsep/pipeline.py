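"""End-to-end orchestration: simulate a study, run every analysis stage, and
assemble a reproducible report.

The default configuration encodes the study conditions the analyses are
designed to recover: a three-level ROI hierarchy (ML, AL, AM) whose
context-free geometries follow view-specific shape (52 deg mean separability),
mirror-symmetric (68 deg), and view-invariant appearance (85 deg) tuning; an
expected condition in which the two lower ROIs inherit the next-higher tuning,
gain extra context dimensions and a shared top-down component (separability
61 / 77.2 deg, AM unchanged); and an unexpected condition built as
expected + a prediction-error component carrying higher-order tuning.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import connectivity as conn
from . import dimensionality as dim
from . import pupil as pup
from . import rsa
from . import separability as sep
from ._rng import child_seed
from .synthdata import (
    GeometrySpec,
    PatternSet,
    StimulusSet,
    build_pairs,
    generate_pupil_trace,
    generate_roi_patterns,
    generate_stimulus_set,
    generate_test_sequence,
    generate_training_sequence,
)

ROIS = ("ML", "AL", "AM")
CONDITIONS = ("context_free", "expected", "unexpected")

# tuning mixtures and target mean angles per (ROI, condition)
DEFAULT_TUNING = {
    ("ML", "context_free"): ({"shape": 1.0}, 52.0, 0),
    ("AL", "context_free"): ({"mirror_symmetry": 1.0}, 68.0, 0),
    ("AM", "context_free"): ({"view_invariant_appearance": 1.0}, 85.0, 0),
    ("ML", "expected"): ({"mirror_symmetry": 1.0}, 61.0, 6),
    ("AL", "expected"): ({"appearance": 0.5, "view_invariant_appearance": 0.5}, 77.2, 6),
    ("AM", "expected"): ({"view_invariant_appearance": 1.0}, 85.0, 0),
}
# prediction-error component tuning per ROI (unexpected = expected + PE)
DEFAULT_PE_TUNING = {
    "ML": {"mirror_symmetry": 1.0},
    "AL": {"appearance": 0.5, "view_invariant_appearance": 0.5},
    "AM": {"view_invariant_appearance": 1.0},
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a full synthetic run."""

    seed: int = 0
    n_voxels: int = 200
    noise_sd: float = 0.4            # per-trial, per-voxel pattern noise
    n_trials_avg: int = 36           # trials averaged into each pattern
    shared_weight: float = 0.5       # top-down shared component, expected cond.
    pe_gain: float = 1.3
    n_test_pairs: int = 90
    proportions: tuple = (0.6, 0.2, 0.2)
    n_boot: int = 10000
    n_perm: int = 1000
    n_conn_boot: int = 2000
    alpha: float = 0.05
    pupil_entrainment: float = 1.0
    pupil_rate_hz: float = 120.0
    n_pupil_runs: int = 6
    pupil_training_repeats: int = 800  # 7200 pairs -> 400 one-epoch blocks
    run_glm: bool = False
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["proportions"] = tuple(raw.get("proportions", (0.6, 0.2, 0.2)))
        return cls(**raw)


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame]
    provenance: dict
    summary: str = ""


def default_geometry_spec(config: RunConfig, roi: str, condition: str) -> GeometrySpec:
    weights, target, ctx = DEFAULT_TUNING[(roi, condition if condition != "unexpected" else "expected")]
    # the shared top-down component carries the top area's own representational
    # format; AM is its source, so only the receiving areas blend it in
    shared = (config.shared_weight
              if condition in ("expected", "unexpected") and roi != "AM" else 0.0)
    return GeometrySpec(
        tuning_weights=weights,
        target_mean_angle=target,
        n_voxels=config.n_voxels,
        extra_context_dims=ctx,
        noise_sd=config.noise_sd,
        n_trials=config.n_trials_avg,
        shared_weight=shared,
        # structural stream is condition-independent: an ROI keeps its voxel
        # projections across conditions; only measurement noise is re-drawn
        seed=child_seed(config.seed, "geometry", roi),
        noise_seed=child_seed(config.seed, "noise", roi, condition),
    )


def simulate_study(config: RunConfig) -> dict:
    """Generate stimuli, design, per-cell ROI patterns, and sequences."""
    stimuli = generate_stimulus_set(seed=child_seed(config.seed, "stimuli"))
    pairs = build_pairs(stimuli, seed=child_seed(config.seed, "pairs"))
    train_seq = generate_training_sequence(pairs, n_repeats=config.pupil_training_repeats,
                                           seed=child_seed(config.seed, "train"))
    test_seq = generate_test_sequence(pairs, proportions=config.proportions,
                                      n_trials=config.n_test_pairs,
                                      seed=child_seed(config.seed, "test"))

    stim_by_cond = {
        "context_free": pairs.predictor_ids(),
        "expected": pairs.successor_ids(),
        "unexpected": pairs.successor_ids(),
    }
    # shared top-down latent, common to all ROIs: the view-invariant
    # appearance geometry of the (successor) faces -- predictions carry the
    # representational format of the top of the hierarchy
    succ_ids = pairs.successor_ids()
    ident = stimuli.select(succ_ids).table["identity"]
    canon = np.array([stimuli.canonical_appearance(int(i)) for i in ident])
    shared = {cond: canon - canon.mean(axis=0, keepdims=True)
              for cond in ("expected", "unexpected")}
    # per-stimulus context coefficients are common across areas (the same
    # predictive-context features reach every ROI; voxel axes stay ROI-specific)
    ctx_coeffs = {cond: np.random.default_rng(child_seed(config.seed, "ctx", cond))
                  .normal(size=(9, 6)) for cond in ("expected", "unexpected")}

    patterns: dict[tuple[str, str], PatternSet] = {}
    for roi in ROIS:
        for cond in ("context_free", "expected"):
            spec = default_geometry_spec(config, roi, cond)
            patterns[(roi, cond)] = generate_roi_patterns(
                stimuli, stim_by_cond[cond], spec, roi=roi, condition=cond,
                shared_latent=shared.get(cond),
                context_coeffs=(ctx_coeffs[cond][:, :spec.extra_context_dims]
                                if cond in ctx_coeffs and spec.extra_context_dims else None))
        # unexpected: regenerate the expected geometry with fresh noise and
        # add a prediction-error component with its own (higher-order) tuning
        pe_spec = GeometrySpec(
            tuning_weights=DEFAULT_PE_TUNING[roi],
            target_mean_angle=85.0,
            n_voxels=config.n_voxels,
            noise_sd=0.0,
            seed=child_seed(config.seed, "pe", roi),
        )
        pe = generate_roi_patterns(stimuli, stim_by_cond["unexpected"], pe_spec,
                                   roi=roi, condition="pe")
        spec_u = default_geometry_spec(config, roi, "unexpected")
        patterns[(roi, "unexpected")] = generate_roi_patterns(
            stimuli, stim_by_cond["unexpected"], spec_u, roi=roi, condition="unexpected",
            shared_latent=shared["unexpected"],
            context_coeffs=(ctx_coeffs["unexpected"][:, :spec_u.extra_context_dims]
                            if spec_u.extra_context_dims else None),
            pe_component=pe, pe_gain=config.pe_gain)

    return {"stimuli": stimuli, "pairs": pairs, "train_seq": train_seq,
            "test_seq": test_seq, "patterns": patterns,
            "stim_by_cond": stim_by_cond}


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------

def separability_stage(patterns: dict, config: RunConfig) -> pd.DataFrame:
    rows = []
    angle_sets = {key: sep.pairwise_angles(ps) for key, ps in patterns.items()}
    mags = {key: sep.population_magnitude(ps) for key, ps in patterns.items()}
    for (roi, cond), aset in angle_sets.items():
        rows.append({
            "roi": roi, "condition": cond, "n_angles": len(aset),
            "mean_angle_deg": sep.circular_mean_angle(aset),
            "mean_norm": mags[(roi, cond)].mean_norm,
        })
    table = pd.DataFrame(rows)

    # condition contrasts per ROI, Holm families grouped per contrast type
    for contrast, test in (
        (("expected", "context_free"), "watson_williams"),
        (("unexpected", "context_free"), "watson_williams"),
        (("unexpected", "expected"), "hotelling_paired"),
    ):
        results = []
        for roi in ROIS:
            a = angle_sets[(roi, contrast[0])].angles
            b = angle_sets[(roi, contrast[1])].angles
            res = (sep.watson_williams(a, b) if test == "watson_williams"
                   else sep.hotelling_paired(a, b))
            results.append(res)
        p_adj = sep.holm_correct([r.p_raw for r in results])
        for roi, res, pa in zip(ROIS, results, p_adj):
            table.loc[len(table)] = {
                "roi": roi, "condition": f"{contrast[0]}_vs_{contrast[1]}",
                "n_angles": res.df[1],
                "mean_angle_deg": np.nan, "mean_norm": np.nan,
            }
            table.loc[len(table) - 1, "statistic"] = res.statistic
            table.loc[len(table) - 1, "p_raw"] = res.p_raw
            table.loc[len(table) - 1, "p_holm"] = pa
            table.loc[len(table) - 1, "test"] = test

    # magnitude-separability decoupling across the 9 cells
    cells = [(roi, cond) for roi in ROIS for cond in CONDITIONS]
    rho, dfree, p = sep.magnitude_separability_decoupling(
        [sep.circular_mean_angle(angle_sets[c]) for c in cells],
        [mags[c].mean_norm for c in cells])
    table.attrs["decoupling"] = {"rho": rho, "df": dfree, "p": p}
    return table


def dimensionality_stage(patterns: dict, config: RunConfig) -> pd.DataFrame:
    rows = []
    results = {}
    for (roi, cond), ps in patterns.items():
        res = dim.pr_noise_ceiling(ps, n_perm=config.n_perm,
                                   seed=child_seed(config.seed, "prceil", roi, cond))
        results[(roi, cond)] = res
        rows.append({"roi": roi, "condition": cond, "pr": res.pr,
                     "ceiling_2.5": float(np.percentile(res.noise_ceiling, 2.5)),
                     "ceiling_97.5": float(np.percentile(res.noise_ceiling, 97.5)),
                     "p_vs_ceiling": res.p_vs_ceiling})
    table = pd.DataFrame(rows)
    for contrast in (("expected", "context_free"), ("unexpected", "expected")):
        ps, diffs = [], []
        for roi in ROIS:
            d, p = dim.compare_pr(patterns[(roi, contrast[0])], patterns[(roi, contrast[1])],
                                  n_perm=config.n_perm,
                                  seed=child_seed(config.seed, "prcmp", roi, *contrast))
            diffs.append(d)
            ps.append(p)
        p_adj = sep.holm_correct(ps)
        for roi, d, p, pa in zip(ROIS, diffs, ps, p_adj):
            table.loc[len(table)] = {"roi": roi,
                                     "condition": f"{contrast[0]}_vs_{contrast[1]}",
                                     "pr": d, "p_vs_ceiling": np.nan}
            table.loc[len(table) - 1, "p_raw"] = p
            table.loc[len(table) - 1, "p_holm"] = pa
    return table


def _model_rdms_for(stimuli: StimulusSet, stim_ids: list[str]) -> dict[str, rsa.RDM]:
    sel = stimuli.select(stim_ids)
    return {
        "shape": rsa.model_rdm_shape(sel),
        "mirror_symmetry": rsa.model_rdm_mirror_symmetry(
            list(sel.table["view"]), list(sel.table["stim_id"])),
        "appearance": rsa.model_rdm_appearance(sel),
        "view_invariant_appearance": rsa.model_rdm_view_invariant_appearance(sel, stimuli),
    }


def rsa_stage(sim: dict, config: RunConfig) -> pd.DataFrame:
    stimuli: StimulusSet = sim["stimuli"]
    patterns = sim["patterns"]
    stim_by_cond = sim["stim_by_cond"]
    candidates = {"ML": "shape", "AL": "mirror_symmetry", "AM": "view_invariant_appearance"}

    models = {c: _model_rdms_for(stimuli, stim_by_cond[c]) for c in ("context_free", "expected")}
    controls = {c: rsa.gabor_control_rdm(stimuli.select(stim_by_cond[c]))
                for c in ("context_free", "expected")}
    first = {key: rsa.first_level_rdm(ps) for key, ps in patterns.items()}

    rows = []
    fits: dict[tuple[str, str], rsa.ModelFitSet] = {}
    for roi in ROIS:
        for cond in ("context_free", "expected"):
            fs = rsa.second_level_fit(first[(roi, cond)], models[cond], controls[cond],
                                      n_boot=config.n_boot,
                                      seed=child_seed(config.seed, "boot", roi, cond))
            fits[(roi, cond)] = fs
            for name, fit in fs.fits.items():
                rows.append({"roi": roi, "condition": cond, "model": name,
                             "rho": fit.rho, "z": fit.z,
                             "z_sem": float(fit.bootstrap_z.std(ddof=1))})
        # identity PE geometry
        _, pe_rdm = rsa.pe_geometry(patterns[(roi, "expected")], patterns[(roi, "unexpected")])
        fs_pe = rsa.second_level_fit(pe_rdm, models["expected"], controls["expected"],
                                     n_boot=config.n_boot,
                                     seed=child_seed(config.seed, "boot", roi, "pe"))
        fits[(roi, "pe_identity")] = fs_pe
        for name, fit in fs_pe.fits.items():
            rows.append({"roi": roi, "condition": "pe_identity", "model": name,
                         "rho": fit.rho, "z": fit.z,
                         "z_sem": float(fit.bootstrap_z.std(ddof=1))})
    table = pd.DataFrame(rows)

    # winning-model test in the context-free condition
    best = {}
    for roi in ROIS:
        diff, p = rsa.best_model_test(fits[(roi, "context_free")], candidates[roi])
        best[roi] = {"candidate": candidates[roi], "difference": diff, "p": p}
    table.attrs["best_model_context_free"] = best

    # tuning-shift tests (expected vs context-free), Raghunathan, one-sided
    shift_rows = []
    shifts = {"ML": [("mirror_symmetry", "increase"), ("shape", "decrease")],
              "AL": [("appearance", "increase"), ("view_invariant_appearance", "increase"),
                     ("mirror_symmetry", "decrease")],
              "AM": [("appearance", "decrease"), ("view_invariant_appearance", "decrease")]}
    for roi, tests_ in shifts.items():
        for model_name, direction in tests_:
            r_jk = fits[(roi, "context_free")].fits[model_name].rho
            r_hm = fits[(roi, "expected")].fits[model_name].rho
            v_model_cf = models["context_free"][model_name].vector()
            v_model_ex = models["expected"][model_name].vector()
            v_rdm_cf = first[(roi, "context_free")].vector()
            v_rdm_ex = first[(roi, "expected")].vector()
            inter = {
                "r_jh": stats.spearmanr(v_model_cf, v_model_ex).statistic,
                "r_jm": stats.spearmanr(v_model_cf, v_rdm_ex).statistic,
                "r_kh": stats.spearmanr(v_rdm_cf, v_model_ex).statistic,
                "r_km": stats.spearmanr(v_rdm_cf, v_rdm_ex).statistic,
            }
            alt = "less" if direction == "increase" else "greater"
            z, p = rsa.raghunathan_test(r_jk, r_hm, inter, n=v_rdm_cf.size, alternative=alt)
            shift_rows.append({"roi": roi, "model": model_name, "direction": direction,
                               "z": z, "p": p})
    table.attrs["tuning_shift_expected_vs_context_free"] = pd.DataFrame(shift_rows)
    return table


def connectivity_stage(sim: dict, config: RunConfig) -> pd.DataFrame:
    stimuli: StimulusSet = sim["stimuli"]
    patterns = sim["patterns"]
    stim_by_cond = sim["stim_by_cond"]
    rows = []
    rdms = {}
    controls = {}
    for cond in ("context_free", "expected"):
        controls[cond] = rsa.gabor_control_rdm(stimuli.select(stim_by_cond[cond]))
        rdms[cond] = {roi: rsa.first_level_rdm(patterns[(roi, cond)]) for roi in ROIS}
        res = conn.pattern_connectivity(rdms[cond], controls[cond], condition=cond)
        rows.append({"condition": cond, "rm_rho": res.rm_rho, "df": res.df, "p": res.p,
                     "n_pairs": res.n_pairs, "n_cells": res.n_cells})
    diff, p = conn.connectivity_condition_contrast(
        rdms["expected"], rdms["context_free"],
        control_a=controls["expected"], control_b=controls["context_free"],
        n_boot=config.n_conn_boot, seed=child_seed(config.seed, "connboot"))
    table = pd.DataFrame(rows)
    table.attrs["expected_vs_context_free"] = {"difference": diff, "p": p}
    return table


def pupil_stage(sim: dict, config: RunConfig) -> pd.DataFrame:
    rows = []
    for run in range(config.n_pupil_runs):
        trace = generate_pupil_trace(
            sim["train_seq"],
            entrainment_strength=config.pupil_entrainment,
            rate_hz=config.pupil_rate_hz,
            seed=child_seed(config.seed, "pupil", run))
        clean = pup.preprocess_pupil(trace)
        epochs = pup.make_pseudo_trials(clean)
        spec = pup.multitaper_itc(epochs, clean.rate_hz)
        norm = pup.normalize_itc(spec, target_freq=0.5)
        freqs, prof = pup.normalized_itc_profile(spec)
        peak = float(freqs[int(np.nanargmax(prof))])
        rows.append({"run": run, "n_epochs": spec.n_pseudo_trials,
                     "normalized_pair_itc": norm, "peak_freq_hz": peak})
    table = pd.DataFrame(rows)
    t, p = pup.itc_significance(table["normalized_pair_itc"].to_numpy())
    table.attrs["itc_t_vs_1"] = {"t": t, "p": p}
    return table


def glm_stage(sim: dict, config: RunConfig) -> pd.DataFrame:
    """Scaled-down LSS demonstration: simulate one BOLD run from the test
    sequence of one ROI and report trial-beta recovery."""
    from .glm import estimate_noise_covariance, fit_lss, hrf_kernel, noise_normalize
    from .synthdata import generate_bold_timeseries, generate_test_sequence

    pairs = sim["pairs"]
    seq = generate_test_sequence(pairs, proportions=(0.6, 0.4, 0.0), n_trials=20,
                                 seed=child_seed(config.seed, "glmseq"))
    ps = sim["patterns"][("ML", "context_free")]
    lookup = {s: ps.data[i] for i, s in enumerate(ps.stim_ids)}
    median = np.median(np.abs(ps.data))
    rng = np.random.default_rng(child_seed(config.seed, "glmbeta"))
    betas = np.array([lookup.get(s, rng.normal(0, median, ps.n_voxels))
                      for s in seq.table["stim_id"]])
    hrf = hrf_kernel(2.0)
    run = generate_bold_timeseries(seq, betas, hrf, noise_sd=0.5,
                                   seed=child_seed(config.seed, "glmnoise"))
    est = fit_lss(run)
    rel = np.linalg.norm(est.betas - betas, axis=1) / np.linalg.norm(betas, axis=1)
    corr = np.array([np.corrcoef(est.betas[i], betas[i])[0, 1]
                     for i in range(betas.shape[0])])
    cov = estimate_noise_covariance(est.residuals)
    white = noise_normalize(PatternSet(data=est.tstats, stim_ids=list(seq.table["stim_id"])),
                            cov)
    return pd.DataFrame({"trial": np.arange(betas.shape[0]),
                         "relative_beta_error": rel,
                         "pattern_correlation": corr,
                         "whitened_t_norm": np.linalg.norm(white.data, axis=1)})


def run_pipeline(config: RunConfig) -> RunReport:
    """simulate -> (optional glm) -> separability -> dimensionality -> rsa ->
    connectivity -> pupil; returns the report and optionally writes tables."""
    t0 = time.time()
    timings = {}
    sim = simulate_study(config)
    timings["simulate"] = time.time() - t0

    tables: dict[str, pd.DataFrame] = {}
    stages = [("separability", lambda: separability_stage(sim["patterns"], config)),
              ("dimensionality", lambda: dimensionality_stage(sim["patterns"], config)),
              ("rsa", lambda: rsa_stage(sim, config)),
              ("connectivity", lambda: connectivity_stage(sim, config)),
              ("pupil", lambda: pupil_stage(sim, config))]
    if config.run_glm:
        stages.insert(0, ("glm", lambda: glm_stage(sim, config)))
    for name, fn in stages:
        ts = time.time()
        tables[name] = fn()
        timings[name] = time.time() - ts

    provenance = {"config": asdict(config), "timings_s": timings}
    lines = ["separability (circular mean angles, deg):"]
    st = tables["separability"]
    for roi in ROIS:
        cells = st[(st["roi"] == roi) & st["condition"].isin(CONDITIONS)]
        vals = ", ".join(f"{c}: {v:.1f}" for c, v in
                         zip(cells["condition"], cells["mean_angle_deg"]))
        lines.append(f"  {roi}: {vals}")
    dt = tables["dimensionality"]
    lines.append("participation ratio:")
    for roi in ROIS:
        cells = dt[(dt["roi"] == roi) & dt["condition"].isin(CONDITIONS)]
        vals = ", ".join(f"{c}: {v:.2f}" for c, v in zip(cells["condition"], cells["pr"]))
        lines.append(f"  {roi}: {vals}")
    best = tables["rsa"].attrs["best_model_context_free"]
    lines.append("context-free winning model per ROI: "
                 + ", ".join(f"{r}: {b['candidate']} (p={b['p']:.4g})" for r, b in best.items()))
    cc = tables["connectivity"].attrs["expected_vs_context_free"]
    lines.append(f"connectivity expected - context-free: {cc['difference']:.4f} (p={cc['p']:.4g})")
    pt = tables["pupil"].attrs["itc_t_vs_1"]
    lines.append(f"pupil normalized pair-frequency ITC vs 1: t={pt['t']:.2f}, p={pt['p']:.4g}")
    summary = "\n".join(lines)

    report = RunReport(tables=tables, provenance=provenance, summary=summary)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        for name, tab in tables.items():
            tab.to_csv(out / f"{name}.csv", index=False)
            extras = {k: v for k, v in tab.attrs.items() if not isinstance(v, pd.DataFrame)}
            if extras:
                (out / f"{name}_stats.json").write_text(json.dumps(extras, default=float))
            for k, v in tab.attrs.items():
                if isinstance(v, pd.DataFrame):
                    v.to_csv(out / f"{name}_{k}.csv", index=False)
        (out / "summary.txt").write_text(summary + "\n")
        (out / "provenance.json").write_text(json.dumps(provenance, default=float))
    return report
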