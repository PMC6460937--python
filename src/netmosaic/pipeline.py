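"""End-to-end orchestration of the multilevel dimorphism analysis.

``run_pipeline`` ties the stages together: synthetic cohort (or loaded
runs) -> equilibration trim + QC -> optional motion matching -> for each
model order {subject PCA -> group PCA -> repeated Infomax + stability
clustering -> guided back-reconstruction -> spectral sorting -> thresholded
network maps -> MANCOVA / voxelwise sex statistics with pooled FDR} ->
association-map footprint -> report. All randomness flows from the
pipeline seed; stages are cached by config hash so a re-run with only the
statistical settings changed does not repeat the ICA.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, SimulationConfig
from .cohort import SyntheticCohort, generate_association_atlas, generate_cohort
from .exceptions import ValidationError
from .footprint import aggregate_unique, binarize_association_map, footprint_table, overlap_voxels
from .ica import (
    concatenate_and_reduce,
    gig_backreconstruct,
    icasso_stabilize,
    infomax_ica,
    reduce_subject,
)
from .netmap import assign_labels, one_sample_tmap, threshold_map
from .qc import compute_dvars, motion_match, qc_report, trim_equilibration
from .spectra import classify_components, component_metrics
from .stats import (
    build_design,
    fdr_correct,
    mancova_reduce,
    model_average_area,
    network_fraction,
    split_directions,
    voxelwise_univariate,
)

__all__ = ["RunManifest", "run_pipeline", "make_report"]


@dataclass
class RunManifest:
    version: str
    seed: int
    stage_hashes: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)     # stage -> summary payload
    timestamps: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "stage_hashes": self.stage_hashes,
                "stages": self.stages,
                "timestamps": self.timestamps,
            },
            indent=2,
            default=str,
        ))


def _hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def _decompose_order(
    runs_matrices: list[np.ndarray],
    order: int,
    k: int,
    n_runs: int,
    seed_seq: np.random.SeedSequence,
):
    """Subject PCA -> group PCA -> repeated Infomax -> stability clustering."""
    reduced = [reduce_subject(x, k)[1] for x in runs_matrices]
    group = concatenate_and_reduce(reduced, order)
    children = seed_seq.spawn(n_runs)
    run_maps = [
        infomax_ica(group["whitened"], np.random.default_rng(cs))["maps"]
        for cs in children
    ]
    return icasso_stabilize(run_maps)


def run_pipeline(
    sim_config: SimulationConfig,
    config: PipelineConfig,
    outdir: str | Path,
    motion_matched: bool = False,
    cohort: SyntheticCohort | None = None,
) -> tuple[RunManifest, dict]:
    """Execute the full workflow; returns the manifest and an in-memory
    results dictionary keyed by stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=config.seed)
    results: dict = {}

    def mark(stage: str, payload: dict, h: str) -> None:
        manifest.stage_hashes[stage] = h
        manifest.stages[stage] = payload
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    # ---- simulate -------------------------------------------------------
    sim_hash = _hash("simulate", asdict(sim_config))
    if cohort is None:
        cohort = generate_cohort(sim_config)
    atlas = generate_association_atlas(sim_config, cohort.truth, config.terms)
    results["cohort"], results["atlas"] = cohort, atlas
    mark("simulate", {"n_subjects": len(cohort.runs)}, sim_hash)

    # ---- qc -------------------------------------------------------------
    truth = cohort.truth
    mask = truth.mask
    runs = [trim_equilibration(r, config.n_trim) for r in cohort.runs]
    report = qc_report(runs, mask, config.correspondence_cutoff, outdir / "qc_report.tsv")
    covariates = cohort.covariates.copy()
    covariates["dvars"] = [compute_dvars(r).mean for r in runs]
    keep = ~report["flagged"].to_numpy()
    results["qc"] = {"report": report, "n_flagged": int((~keep).sum())}
    mark("qc", {"n_flagged": int((~keep).sum()), "n_timepoints": runs[0].n_timepoints},
         _hash("qc", sim_hash, config.n_trim, config.correspondence_cutoff))

    if motion_matched:
        kept_ids, removed = motion_match(covariates, config.motion_match_alpha)
        (outdir / "removed_subjects.txt").write_text("\n".join(removed) + "\n")
        sel = covariates["subject_id"].isin(kept_ids).to_numpy()
        runs = [r for r, s in zip(runs, sel) if s]
        covariates = covariates[sel].reset_index(drop=True)
        results["motion_match"] = {"removed": removed}

    design = build_design(covariates)
    mask_idx = np.flatnonzero(mask.ravel())
    run_matrices = [r.in_mask_matrix().astype(float) for r in runs]

    # ---- per model order ------------------------------------------------
    seed_root = np.random.SeedSequence(config.seed)
    per_order: dict[int, dict] = {}
    all_overlaps = {}
    for order_i, (order, k) in enumerate(sorted(config.model_orders.items())):
        ica_hash = _hash("ica", sim_hash, order, k, config.n_ica_runs, config.seed)
        cache = outdir / f"ica_order{order}.npz"
        if cache.exists():
            cached = np.load(cache, allow_pickle=False)
            if str(cached["hash"]) == ica_hash:
                group_maps = cached["group_maps"]
                stability = cached["stability"]
            else:
                group_maps = None
        else:
            group_maps = None
        if group_maps is None:
            decomp = _decompose_order(
                run_matrices, order, k, config.n_ica_runs,
                np.random.SeedSequence([config.seed, order_i]),
            )
            group_maps, stability = decomp.group_maps, decomp.stability_index
            np.savez(cache, hash=ica_hash, group_maps=group_maps, stability=stability)
        mark(f"ica_order{order}", {"stability_mean": float(np.mean(stability))}, ica_hash)

        subj = [
            gig_backreconstruct(x, group_maps, subject_id=r.subject_id)
            for x, r in zip(run_matrices, runs)
        ]
        subj_maps = np.stack([s.subject_maps for s in subj])      # S x C x Vmask
        subj_tcs = np.stack([s.subject_timecourses for s in subj])

        # sorting: subject-averaged component spectra, group-map geometry
        gm_flat = truth.gm_mask.ravel()[mask_idx]
        metrics = [
            component_metrics(
                group_maps[c], subj_tcs[:, c, :], runs[0].tr_seconds, gm_flat
            )
            for c in range(order)
        ]
        labels = classify_components(
            metrics, falff_min=config.falff_min, gm_overlap_min=config.gm_overlap_min
        )
        neural = [l.component for l in labels if l.decision == "neural"]

        networks = []
        effects_tables = []
        for net_id in neural:
            tmap, _ = one_sample_tmap(subj_maps[:, net_id, :])
            net = threshold_map(tmap, network_id=net_id, multiplier=config.threshold_multiplier)
            if net.n_voxels == 0:
                continue
            networks.append(net)
            red = mancova_reduce(subj_maps[:, net_id, :][:, net.voxels], design,
                                 alpha_keep=config.alpha_keep)
            eff = voxelwise_univariate(
                subj_maps[:, net_id, :][:, net.voxels],
                design,
                red,
                network_id=net_id,
                voxel_indices=mask_idx[net.voxels],
            )
            effects_tables.append(eff)
        assign_labels(networks)
        effects = (
            fdr_correct(pd.concat(effects_tables, ignore_index=True), config.fdr_level)
            if effects_tables
            else fdr_correct(pd.DataFrame(columns=["network", "voxel", "beta", "t", "p"]))
        )
        summaries = []
        grid = truth.config.grid_shape
        for net in networks:
            sub = effects[effects["network"] == net.network_id]
            summaries.append(
                network_fraction(net, sub, grid, config.connectivity)
            )
        per_order[order] = {
            "group_maps": group_maps,
            "stability": stability,
            "labels": labels,
            "networks": networks,
            "effects": effects,
            "summaries": summaries,
            "average_area": model_average_area(summaries) if summaries else {},
        }
        effects.to_csv(outdir / f"effects_order{order}.tsv", sep="\t", index=False)

        # footprint inputs: per-network directional effect sets in grid space
        overlaps = []
        assoc = {
            t: binarize_association_map(atlas.maps[t], t) for t in atlas.term_names
        }
        sig = effects[effects["significant"]] if len(effects) else effects
        for net in networks:
            sub = sig[sig["network"] == net.network_id]
            f_gt, m_gt = split_directions(sub)
            for direction, d_sub in (("F>M", f_gt), ("M>F", m_gt)):
                for t in atlas.term_names:
                    overlaps.append(
                        overlap_voxels(
                            d_sub["voxel"].to_numpy(), assoc[t], grid,
                            net.network_id, direction,
                        )
                    )
        unique = aggregate_unique(overlaps)
        table = footprint_table(unique, list(atlas.term_names))
        table["model_order"] = order
        per_order[order]["footprint"] = table
        all_overlaps[order] = unique
        table.to_csv(outdir / f"footprint_order{order}.tsv", sep="\t", index=False)
        mark(
            f"stats_order{order}",
            {
                "n_networks": len(networks),
                "n_significant": int(sig["voxel"].nunique()) if len(sig) else 0,
            },
            _hash("stats", ica_hash, config.fdr_level, config.alpha_keep,
                  config.threshold_multiplier),
        )

    results["per_order"] = per_order
    report_text = make_report(manifest, per_order)
    (outdir / "report.md").write_text(report_text)
    manifest.save(outdir / "manifest.json")
    results["report"] = report_text
    return manifest, results


def make_report(manifest: RunManifest, per_order: dict) -> str:
    """Human-readable summary: per-network effect sizes and fractions,
    per-model dimorphic-location counts, per-term footprints."""
    lines = [
        "# Dimorphism analysis report",
        "",
        f"pipeline version {manifest.version}, seed {manifest.seed}",
        "",
    ]
    if not per_order:
        lines.append("No model orders were analyzed.")
        return "\n".join(lines)
    for order, res in sorted(per_order.items()):
        lines.append(f"## Model order {order}")
        n_nets = len(res["networks"])
        sig = res["effects"]
        n_sig = int(sig["significant"].sum()) if len(sig) else 0
        lines.append(f"- retained networks: {n_nets}")
        lines.append(f"- dimorphic locations (significant voxels): {n_sig}")
        if n_sig == 0:
            lines.append("- zero dimorphic locations detected")
        if res["summaries"]:
            lines.append("")
            lines.append("| network | dir | voxels | fraction | mean beta |")
            lines.append("|---|---|---|---|---|")
            for s in res["summaries"]:
                for d, payload in s.per_direction.items():
                    lines.append(
                        f"| {s.network_id} | {d} | {payload['count']} | "
                        f"{payload['fraction']:.4f} | {payload['mean_beta']:.3f} |"
                    )
            avg = res.get("average_area", {})
            if avg:
                lines.append(
                    "- average area: "
                    + ", ".join(f"{d}: {v:.4f}" for d, v in avg.items())
                )
        if "footprint" in res and len(res["footprint"]):
            lines.append("")
            lines.append("| term | F>M | M>F | pct diff |")
            lines.append("|---|---|---|---|")
            for _, row in res["footprint"].iterrows():
                lines.append(
                    f"| {row['term']} | {row['f_count']} | {row['m_count']} | "
                    f"{row['pct_difference']:.1f} |"
                )
        lines.append("")
    return "\n".join(lines)
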