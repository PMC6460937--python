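"""Desk-scale validation experiments.

Each function sets up a fully ground-truthed synthetic study, runs the
relevant pipeline stages, and measures how well the method recovers what
was planted: ICA source recovery, sorting accuracy, threshold-tail
calibration, false-discovery control, directional effect recovery, guided
back-reconstruction fidelity, and the end-to-end footprint identity. The
problem sizes are scaled to a single CPU (grids of ~10^3-10^4 voxels,
tens of subjects) while keeping the study's design constants — two sex
groups, TR = 3 s, ~120 timepoints, low-frequency network sources against
high-frequency artefacts.

Both the test suite and ``scripts/acceptance.py`` drive these functions,
so every reported number is recomputed from scratch at call time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SimulationConfig
from .cohort import generate_association_atlas, generate_cohort
from .footprint import aggregate_unique, binarize_association_map, footprint_table, overlap_voxels
from .ica import (
    concatenate_and_reduce,
    dual_regression,
    gig_backreconstruct,
    icasso_stabilize,
    infomax_ica,
    match_components,
    reduce_subject,
    zscore_rows,
)
from .netmap import threshold_map
from .qc import trim_equilibration
from .spectra import classify_components, component_metrics
from .stats import build_design, connected_clusters, fdr_correct, split_directions, voxelwise_univariate

__all__ = [
    "trim_check",
    "ica_recovery",
    "sorting_accuracy",
    "flat_spectrum_metrics",
    "threshold_tail",
    "fdr_calibration",
    "effect_recovery",
    "gig_vs_dual_regression",
    "footprint_truth_recovery",
    "mosaic_recovery",
    "asymmetric_footprint",
]


# ---------------------------------------------------------------------------
# shared study set-ups

def _ica_cohort_config(seed: int) -> SimulationConfig:
    """The 40-subject decomposition benchmark: 6 network + 3 artefact
    sources on a 20x20x12 grid, 120 timepoints at TR = 3 s."""
    return SimulationConfig(
        n_subjects_per_sex=20,
        n_timepoints=120,
        grid_shape=(20, 20, 12),
        n_neural_sources=6,
        n_noise_sources=3,
        rng_seed=seed,
    )


def _stats_config(seed: int, n_per_sex: int, sex_effect_betas=None, **overrides) -> SimulationConfig:
    """Scaled statistics benchmark: 12x12x8 grid, 3 network + 2 artefact
    sources, 60 timepoints."""
    kwargs = dict(
        n_subjects_per_sex=n_per_sex,
        n_timepoints=60,
        grid_shape=(12, 12, 8),
        n_neural_sources=3,
        n_noise_sources=2,
        sex_effect_betas=sex_effect_betas,
        rng_seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _decompose(cohort, order: int, k: int, n_runs: int, seed: int):
    mats = [r.in_mask_matrix().astype(float) for r in cohort.runs]
    reduced = [reduce_subject(m, k)[1] for m in mats]
    group = concatenate_and_reduce(reduced, order)
    children = np.random.SeedSequence([seed, 101]).spawn(n_runs)
    maps = [
        infomax_ica(group["whitened"], seed=np.random.default_rng(cs))["maps"]
        for cs in children
    ]
    return icasso_stabilize(maps), mats


def _subject_maps_via_dual_regression(cohort) -> tuple[np.ndarray, np.ndarray]:
    """S x C x Vmask subject maps for the planted network sources, on the
    data's intensity scale (unit-variance stage-1 timecourses)."""
    truth = cohort.truth
    mask_idx = np.flatnonzero(truth.mask.ravel())
    refs, _ = zscore_rows(truth.source_maps[:, mask_idx])
    maps = []
    for run in cohort.runs:
        x = run.in_mask_matrix().astype(float)
        x = x - x.mean(axis=0, keepdims=True)
        m, _ = dual_regression(x, refs, normalize_timecourses=True)
        maps.append(m)
    return np.stack(maps), mask_idx


def _detect_effects(
    cohort, q_level: float = 0.01, use_truth_maps: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Voxelwise sex statistics on back-reconstructed network maps, pooled
    BH across the planted network components. Voxel ids are grid-flat.

    With ``use_truth_maps`` the generator's per-subject maps stand in for
    back-reconstruction (the exact output an error-free reconstruction
    would give) — used by the noise-free identity check, where any
    numerical remixing would otherwise register as significant.
    """
    if use_truth_maps:
        mask_idx = np.flatnonzero(cohort.truth.mask.ravel())
        subj_maps = cohort.truth.subject_maps[:, :, mask_idx].astype(float)
    else:
        subj_maps, mask_idx = _subject_maps_via_dual_regression(cohort)
    design = build_design(cohort.covariates)
    tables = []
    for c in cohort.truth.neural_indices:
        tables.append(
            voxelwise_univariate(
                subj_maps[:, c, :], design, network_id=int(c), voxel_indices=mask_idx
            )
        )
    effects = fdr_correct(pd.concat(tables, ignore_index=True), q_level)
    return effects, mask_idx


# ---------------------------------------------------------------------------
# experiments

def trim_check(seed: int = 0) -> dict:
    """Equilibration trim on a 124-volume synthetic run."""
    cfg = SimulationConfig(
        n_subjects_per_sex=1, n_timepoints=124, grid_shape=(10, 10, 6),
        n_neural_sources=1, n_noise_sources=1, rng_seed=seed,
    )
    run = generate_cohort(cfg).runs[0]
    trimmed = trim_equilibration(run, 4)
    return {"n_before": run.n_timepoints, "n_after": trimmed.n_timepoints}


def ica_recovery(seed: int, n_seeds: int = 5, order: int = 9, k: int = 20,
                 n_runs: int = 10) -> dict:
    """Stabilized group-map recovery of the 9 planted sources, per seed."""
    recovered, min_r = [], []
    for i in range(n_seeds):
        cohort = generate_cohort(_ica_cohort_config(seed + i))
        dec, _ = _decompose(cohort, order, k, n_runs, seed + i)
        mask_idx = np.flatnonzero(cohort.truth.mask.ravel())
        _, _, rvals = match_components(
            cohort.truth.source_maps[:, mask_idx], dec.group_maps
        )
        recovered.append(int((rvals >= 0.9).sum()))
        min_r.append(float(rvals.min()))
    return {
        "n_sources": 9,
        "recovered_per_seed": recovered,
        "min_matched_r_per_seed": min_r,
        "min_recovered": min(recovered),
    }


def sorting_accuracy(seed: int, n_seeds: int = 10) -> dict:
    """Neural/artefact classification accuracy against generator truth.

    Metrics use the planted components: z-scored source maps for geometry
    and the cohort's per-subject timecourses (spectra averaged over
    subjects), i.e. the conditions the band-power contract guarantees.
    """
    total = correct = 0
    for i in range(n_seeds):
        cfg = _ica_cohort_config(seed + i)
        cohort = generate_cohort(cfg)
        truth = cohort.truth
        mask_idx = np.flatnonzero(truth.mask.ravel())
        gm_flat = truth.gm_mask.ravel()[mask_idx]
        zmaps, _ = zscore_rows(truth.source_maps[:, mask_idx])
        metrics = [
            component_metrics(
                zmaps[c], truth.subject_timecourses[:, c, :], cfg.tr_seconds, gm_flat
            )
            for c in range(cfg.n_sources)
        ]
        labels = classify_components(metrics)
        for c in range(cfg.n_sources):
            expected = "neural" if c in truth.neural_indices else "artefact"
            correct += labels[c].decision == expected
            total += 1
    return {"accuracy": correct / total, "n_components": total}


def flat_spectrum_metrics() -> dict:
    """fALFF ratio and dynamic range of an exactly flat spectrum."""
    from .spectra import compute_dynamic_range, compute_falff_ratio

    freqs = np.linspace(0.0, 0.25, 501)
    power = np.full_like(freqs, 3.0)
    falff = compute_falff_ratio(freqs, power)
    drange, _ = compute_dynamic_range(freqs, power)
    return {"falff_ratio": float(falff), "dynamic_range": float(drange)}


def threshold_tail(seed: int, n_voxels: int = 10**6) -> dict:
    """Retained fraction of a standard-normal t-map under mean + 4 sigma."""
    rng = np.random.default_rng(seed)
    t_map = rng.standard_normal(n_voxels)
    net = threshold_map(t_map, multiplier=4.0)
    p_tail = float(norm.sf(4.0))
    se = float(np.sqrt(p_tail * (1 - p_tail) / n_voxels))
    return {
        "retained_fraction": net.n_voxels / n_voxels,
        "expected_tail": p_tail,
        "binomial_se": se,
        "within_3se": bool(abs(net.n_voxels / n_voxels - p_tail) <= 3 * se),
    }


def fdr_calibration(seed: int, n_cohorts: int = 200, n_per_sex: int = 30,
                    q_level: float = 0.01) -> dict:
    """Mean voxelwise false-discovery proportion over null cohorts.

    No sex effect is planted, so every discovery is false and the FDP of a
    cohort is 1 when anything is declared significant.
    """
    fdps = []
    for i in range(n_cohorts):
        cohort = generate_cohort(_stats_config(seed + i, n_per_sex))
        effects, _ = _detect_effects(cohort, q_level)
        n_sig = int(effects["significant"].sum())
        fdps.append(1.0 if n_sig > 0 else 0.0)
    mean_fdp = float(np.mean(fdps))
    mc_se = float(np.sqrt(q_level * (1 - q_level) / n_cohorts))
    return {
        "mean_fdp": mean_fdp,
        "bound": q_level + 3 * mc_se,
        "n_cohorts": n_cohorts,
    }


def effect_recovery(seed: int, n_reps: int = 50, n_per_sex: int = 50,
                    beta: float = 1.0) -> dict:
    """Detection, direction accuracy and cluster effect-size recovery for
    planted effects of |beta| = 1.0 x noise_sd at 50 subjects/sex."""
    detected = planted_total = 0
    direction_ok = direction_total = 0
    beta_err = []
    for i in range(n_reps):
        cfg = _stats_config(
            seed + i, n_per_sex,
            sex_effect_betas={0: [beta] * 6, 1: [-beta] * 6},
        )
        cohort = generate_cohort(cfg)
        effects, _ = _detect_effects(cohort)
        sig = effects[effects["significant"]]
        truth = cohort.truth
        grid = cfg.grid_shape
        for src, (vox, betas) in truth.sex_effects.items():
            hits = sig[(sig["network"] == src) & sig["voxel"].isin(vox)]
            planted_total += len(vox)
            detected += len(hits)
            true_sign = np.sign(betas[0])
            direction_ok += int((np.sign(hits["beta"]) == true_sign).sum())
            direction_total += len(hits)
            # cluster-average effect size vs planted beta
            f_gt, m_gt = split_directions(sig[sig["network"] == src])
            sub = f_gt if true_sign > 0 else m_gt
            own = sub[sub["voxel"].isin(vox)]
            if len(own):
                clusters = connected_clusters(
                    own["voxel"].to_numpy(), own["beta"].to_numpy(), grid
                )
                mean_beta = np.mean([c.mean_beta for c in clusters])
                beta_err.append(abs(abs(mean_beta) - beta) / beta)
    return {
        "detection_rate": detected / planted_total,
        "direction_accuracy": direction_ok / max(direction_total, 1),
        "mean_cluster_beta_rel_error": float(np.mean(beta_err)),
        "n_replicates": n_reps,
    }


def gig_vs_dual_regression(seed: int, n_seeds: int = 2) -> dict:
    """Median |r| between guided back-reconstruction and the dual
    regression estimate across subjects and components."""
    rs = []
    for i in range(n_seeds):
        cohort = generate_cohort(_ica_cohort_config(seed + i))
        dec, mats = _decompose(cohort, 9, 20, 5, seed + i)
        for m in mats:
            x = m - m.mean(axis=0, keepdims=True)
            sd = gig_backreconstruct(x, dec.group_maps)
            dr_maps, _ = dual_regression(x, dec.group_maps)
            drz, _ = zscore_rows(dr_maps)
            for c in range(9):
                rs.append(abs(np.corrcoef(sd.subject_maps[c], drz[c])[0, 1]))
    return {"median_r": float(np.median(rs)), "n_pairs": len(rs)}


def _footprint_from_effects(cohort, atlas, effects) -> pd.DataFrame:
    grid = cohort.truth.config.grid_shape
    sig = effects[effects["significant"]]
    overlaps = []
    for term in atlas.term_names:
        amap = binarize_association_map(atlas.maps[term], term)
        for net in np.unique(sig["network"]) if len(sig) else []:
            sub = sig[sig["network"] == net]
            f_gt, m_gt = split_directions(sub)
            for direction, d_sub in (("F>M", f_gt), ("M>F", m_gt)):
                overlaps.append(
                    overlap_voxels(
                        d_sub["voxel"].to_numpy(), amap, grid, int(net), direction
                    )
                )
    unique = aggregate_unique(overlaps)
    return footprint_table(unique, list(atlas.term_names))


def footprint_truth_recovery(seed: int) -> dict:
    """End-to-end footprint identity in the noise-free high-beta regime.

    With near-zero noise and large planted betas, detection recovers the
    planted voxel sets exactly, and the per-term unique dimorphic counts
    must equal the generator's brute-force truth overlaps.
    """
    cfg = _stats_config(
        seed, 25,
        sex_effect_betas={0: [3.0] * 8, 1: [-3.0] * 8},
        noise_sd=0.0,
        subject_map_sd=0.0,
    )
    cohort = generate_cohort(cfg)
    atlas = generate_association_atlas(cfg, cohort.truth)
    effects, _ = _detect_effects(cohort, use_truth_maps=True)
    sig = effects[effects["significant"]]
    planted = set(cohort.truth.effect_voxels.tolist())
    detected = set(sig["voxel"].tolist())
    table = _footprint_from_effects(cohort, atlas, effects)
    matches = 0
    for term in atlas.term_names:
        row = table[table["term"] == term]
        n_pipeline = int(row["f_count"].item() + row["m_count"].item())
        matches += n_pipeline == len(atlas.truth_overlap[term])
    return {
        "detection_equals_planted": detected == planted,
        "terms_matching_truth": matches,
        "n_terms": len(atlas.term_names),
    }


def mosaic_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Both-direction effects planted inside one network are recovered as
    a mosaic (non-empty F>M and M>F sets in that network)."""
    hits = 0
    for i in range(n_seeds):
        cfg = _stats_config(
            seed + i, 30,
            sex_effect_betas={0: [0.8] * 5 + [-0.8] * 5},
        )
        cohort = generate_cohort(cfg)
        effects, _ = _detect_effects(cohort)
        sig = effects[effects["significant"] & (effects["network"] == 0)]
        f_gt, m_gt = split_directions(sig)
        hits += (len(f_gt) > 0) and (len(m_gt) > 0)
    return {"fraction_with_mosaic": hits / n_seeds, "n_seeds": n_seeds}


def asymmetric_footprint(seed: int, n_seeds: int = 10) -> dict:
    """Many small M>F plants vs few large F>M plants: the male footprint
    should exceed the female footprint for every term."""
    all_terms_ok = 0
    for i in range(n_seeds):
        cfg = _stats_config(
            seed + i, 30,
            sex_effect_betas={0: [1.5] * 6, 1: [-0.8] * 15, 2: [-0.8] * 15},
        )
        cohort = generate_cohort(cfg)
        atlas = generate_association_atlas(
            cfg, cohort.truth, overlap_fraction=0.8, include_planted_probability=1.0
        )
        effects, _ = _detect_effects(cohort)
        table = _footprint_from_effects(cohort, atlas, effects)
        all_terms_ok += bool((table["m_count"] > table["f_count"]).all())
    return {"fraction_male_larger_all_terms": all_terms_ok / n_seeds, "n_seeds": n_seeds}
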