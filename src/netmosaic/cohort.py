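"""Synthetic BOLD cohort generator with fully known ground truth.

Every downstream stage (QC, group ICA, component sorting, voxelwise sex
statistics, footprint mapping) is exercised against cohorts produced here,
so the generator records everything it plants: source spatial maps, per
subject maps and timecourses, the voxels carrying sex effects and their
signed magnitudes, and per-term association-map overlaps.

The generative model is a linear mixing model per subject::

    X_s (T x V) = TC_s^T (T x C) @ A_s (C x V) + sigma_s * E

where ``A_s`` are smooth spatial source maps with additive subject, sex and
covariate structure, ``TC_s`` are band-limited timecourses (low-frequency
for network sources, high-frequency for artefact sources), and ``E`` is
white Gaussian noise confined to the brain mask. Sex effects are additive
shifts on female subject-map intensity at planted voxels, so a positive
planted beta is an F > M effect under the F = 1 / M = 0 coding used by the
statistics stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import DEFAULT_TERMS, SimulationConfig
from .exceptions import SizingError, ValidationError
from .qc import BoldRun

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "SyntheticAssociationAtlas",
    "ellipsoid_mask",
    "gray_matter_mask",
    "generate_source_maps",
    "generate_timecourses",
    "generate_cohort",
    "generate_association_atlas",
    "write_cohort",
    "write_atlas",
]

#: Gaussian blob width for planted network sources, in voxels.
SOURCE_FWHM = 3.0
_SIGMA = SOURCE_FWHM / 2.3548
#: Blobs are truncated at this radius (in sigmas) so sources have sparse,
#: exactly-zero backgrounds and distant sources are exactly uncorrelated.
_TRUNC = 3.0


# ---------------------------------------------------------------------------
# masks

def ellipsoid_mask(grid_shape: Sequence[int]) -> np.ndarray:
    """Ellipsoidal brain mask inscribed in the grid."""
    nx, ny, nz = grid_shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = (
        ((x - cx) / max(nx / 2, 1)) ** 2
        + ((y - cy) / max(ny / 2, 1)) ** 2
        + ((z - cz) / max(nz / 2, 1)) ** 2
    )
    return r <= 1.0


def gray_matter_mask(mask: np.ndarray, erosion: int = 1) -> np.ndarray:
    """Interior of the brain mask; the rim (mask minus interior) stands in
    for CSF / vascular / edge territory that artefact sources occupy."""
    gm = ndimage.binary_erosion(mask, iterations=erosion)
    if not gm.any():
        return mask.copy()
    return gm


# ---------------------------------------------------------------------------
# ground-truth containers

@dataclass
class GroundTruth:
    """Everything the generator planted, for use as test oracles."""

    config: SimulationConfig
    mask: np.ndarray                      # 3D bool
    gm_mask: np.ndarray                   # 3D bool
    source_maps: np.ndarray               # C x V
    neural_indices: np.ndarray            # indices of network sources
    noise_indices: np.ndarray             # indices of artefact sources
    sex_effects: dict                     # source -> (voxel idx array, beta array)
    subject_maps: np.ndarray              # S x C x V (per-subject A_s)
    subject_timecourses: np.ndarray       # S x C x T

    @property
    def effect_voxels(self) -> np.ndarray:
        """Union of all planted sex-effect voxels (sorted flat indices)."""
        if not self.sex_effects:
            return np.empty(0, dtype=np.intp)
        return np.unique(
            np.concatenate([np.asarray(v, dtype=np.intp) for v, _ in self.sex_effects.values()])
        )

    def effect_voxels_by_sign(self, positive: bool) -> np.ndarray:
        """Planted voxels with positive (F > M) or negative (M > F) betas."""
        out = []
        for vox, betas in self.sex_effects.values():
            vox = np.asarray(vox, dtype=np.intp)
            betas = np.broadcast_to(np.asarray(betas, dtype=float), vox.shape)
            out.append(vox[betas > 0] if positive else vox[betas < 0])
        if not out:
            return np.empty(0, dtype=np.intp)
        return np.unique(np.concatenate(out))


@dataclass
class SyntheticCohort:
    runs: list[BoldRun]
    covariates: pd.DataFrame
    truth: GroundTruth

    def __post_init__(self) -> None:
        if len(self.runs) != len(self.covariates):
            raise ValidationError("one run per covariate row is required")


@dataclass
class SyntheticAssociationAtlas:
    term_names: list[str]
    maps: dict                 # term -> 3D z-map
    truth_overlap: dict        # term -> sorted flat voxel indices


# ---------------------------------------------------------------------------
# source maps

def _place_centers(
    gm: np.ndarray, n: int, min_dist: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample blob centers inside the gray-matter interior with a
    minimum pairwise distance, so planted networks barely overlap."""
    coords = np.argwhere(gm)
    if coords.shape[0] < n:
        raise SizingError(f"grid too small to place {n} sources")
    dist = min_dist
    for restart in range(40):
        centers: list[np.ndarray] = []
        for _ in range(400):
            cand = coords[rng.integers(coords.shape[0])]
            if all(np.linalg.norm(cand - c) >= dist for c in centers):
                centers.append(cand)
                if len(centers) == n:
                    return np.array(centers)
        # a jammed configuration: retry, shrinking the spacing a little but
        # never below one FWHM (sources stay distinguishable on small grids)
        dist = max(dist * 0.9, SOURCE_FWHM)
    raise SizingError(
        f"could not place {n} sources at pairwise distance >= {dist:.1f} "
        f"in a {gm.shape} grid"
    )


def _gaussian_blob(grid_shape: Sequence[int], center: np.ndarray, amplitude: float) -> np.ndarray:
    nx, ny, nz = grid_shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    blob = amplitude * np.exp(-d2 / (2 * _SIGMA**2))
    blob[d2 > (_TRUNC * _SIGMA) ** 2] = 0.0
    return blob


def generate_source_maps(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Planted source spatial maps, shape (n_sources, V).

    Network sources are truncated 3D Gaussian blobs (FWHM ~3 voxels) at
    random interior centers; artefact sources cycle through rim bands,
    rim-weighted speckle, and alternating-plane stripe patterns, mimicking
    the edge/CSF/motion geometry that the sorting metrics discriminate.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    mask = ellipsoid_mask(config.grid_shape)
    gm = gray_matter_mask(mask)
    rim = mask & ~gm
    amp = config.source_amplitude
    maps = np.zeros((config.n_sources, config.n_voxels))

    if config.n_neural_sources:
        # centers sit deeper than the gm boundary so truncated blobs stay
        # predominantly inside gray matter
        interior = gray_matter_mask(mask, erosion=2)
        centers = _place_centers(interior, config.n_neural_sources, 2.0 * SOURCE_FWHM, rng)
        for i, c in enumerate(centers):
            blob = _gaussian_blob(config.grid_shape, c, amp) * mask
            maps[i] = blob.ravel()

    flat_mask = mask.ravel()
    rim_flat = rim.ravel() if rim.any() else flat_mask
    for j in range(config.n_noise_sources):
        idx = config.n_neural_sources + j
        kind = j % 3
        vol = np.zeros(config.n_voxels)
        if kind == 0:  # rim band with smooth modulation
            mod = ndimage.gaussian_filter(
                rng.standard_normal(config.grid_shape), sigma=2.0
            ).ravel()
            vol[rim_flat] = amp * (1.0 + 0.5 * mod[rim_flat] / max(np.abs(mod).max(), 1e-12))
        elif kind == 1:  # salt-and-pepper speckle, weighted toward the rim
            n_spk = max(8, int(0.05 * flat_mask.sum()))
            rim_idx = np.flatnonzero(rim_flat)
            any_idx = np.flatnonzero(flat_mask)
            n_rim = min(len(rim_idx), int(0.7 * n_spk))
            chosen = np.concatenate([
                rng.choice(rim_idx, size=n_rim, replace=False),
                rng.choice(any_idx, size=n_spk - n_rim, replace=False),
            ])
            vol[chosen] = amp * rng.choice([-1.0, 1.0], size=len(chosen))
        else:  # scattered small rim patches, motion-ring-like
            rim_idx = np.flatnonzero(rim_flat)
            patch_centers = rng.choice(rim_idx, size=min(6, len(rim_idx)), replace=False)
            patch = np.zeros(config.grid_shape)
            for pc in patch_centers:
                center = np.array(np.unravel_index(pc, config.grid_shape))
                patch += _gaussian_blob(config.grid_shape, center, 1.0)
            vol = amp * (patch.ravel() * flat_mask)
        maps[idx] = vol
    return maps


# ---------------------------------------------------------------------------
# timecourses

def _band_limited_series(
    n_timepoints: int,
    tr_seconds: float,
    rng: np.random.Generator,
    low_frequency: bool,
) -> np.ndarray:
    """Unit-variance series synthesized in the Fourier domain.

    Magnitudes follow a deterministic spectral envelope (randomness enters
    through the phases) so the spectral shape is controlled: network
    sources have a smooth low-frequency envelope peaking at the lowest
    bin and decaying past 0.10 Hz (peaked spectrum, large dynamic range);
    artefact sources have a weak flat floor plus a ramp that peaks at the
    Nyquist bin (power concentrated at/above 0.15 Hz, near-zero dynamic
    range — the flat/high-frequency signature of noise components).
    """
    freqs = np.fft.rfftfreq(n_timepoints, tr_seconds)
    nyquist = freqs[-1]
    if low_frequency:
        band = (freqs > 0) & (freqs < 0.10)
    else:
        band = freqs >= 0.15
    if not band.any():
        which = "below 0.10 Hz" if low_frequency else "at or above 0.15 Hz"
        raise SizingError(
            f"no frequency bins {which}: series too short or TR too long "
            f"(T={n_timepoints}, TR={tr_seconds}s, Nyquist={nyquist:.4f} Hz)"
        )
    if low_frequency:
        weights = np.where(band, 1.0 / (1.0 + (freqs / 0.03) ** 2), 0.03)
    else:
        lo = min(0.155, nyquist)  # keep window leakage from crossing 0.15 Hz
        support = freqs >= lo
        span = max(nyquist - lo, 1e-9)
        ramp = 0.25 + 0.75 * ((freqs - lo) / span) ** 2
        weights = np.where(support, ramp, 0.05)
    weights[0] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    coef = weights * np.exp(1j * phases)
    if n_timepoints % 2 == 0:
        coef[-1] = weights[-1] * np.sign(rng.standard_normal())
    x = np.fft.irfft(coef, n=n_timepoints)
    x -= x.mean()
    sd = x.std()
    if sd <= 0:  # essentially impossible with continuous draws; retry once
        return _band_limited_series(n_timepoints, tr_seconds, rng, low_frequency)
    return x / sd


def generate_timecourses(
    config: SimulationConfig,
    sex: str = "F",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-source timecourses, shape (n_sources, T), zero mean unit variance.

    ``sex`` is accepted for interface symmetry with the cohort builder; the
    timecourse distribution is identical for both groups because planted sex
    effects act on spatial maps, not on temporal dynamics.
    """
    del sex
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    tcs = np.empty((config.n_sources, config.n_timepoints))
    for i in range(config.n_neural_sources):
        tcs[i] = _band_limited_series(config.n_timepoints, config.tr_seconds, rng, True)
    for j in range(config.n_noise_sources):
        tcs[config.n_neural_sources + j] = _band_limited_series(
            config.n_timepoints, config.tr_seconds, rng, False
        )
    return tcs


# ---------------------------------------------------------------------------
# cohort assembly

_AGE_BINS = np.arange(19, 36, 2)  # 2-year bins spanning 19-35
_IQ_MEAN, _IQ_SD = 114.0, 8.0
_N_SCANNERS = 5


def _default_sex_effects(
    config: SimulationConfig,
    source_maps: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Resolve the planted sex effects; auto-place voxels on source support
    when the config gives betas without explicit voxel sets."""
    effects: dict = {}
    vox_cfg = dict(config.sex_effect_voxels or {})
    beta_cfg = dict(config.sex_effect_betas or {})
    for src in sorted(set(vox_cfg) | set(beta_cfg)):
        betas = np.atleast_1d(np.asarray(beta_cfg.get(src, 0.0), dtype=float))
        if src in vox_cfg:
            vox = np.asarray(vox_cfg[src], dtype=np.intp)
        else:
            support = np.flatnonzero(source_maps[src] != 0)
            if support.size == 0:
                raise ValidationError(f"source {src} has empty support")
            n_pick = min(len(betas), support.size) if len(betas) > 1 else min(8, support.size)
            vox = np.sort(rng.choice(support, size=n_pick, replace=False))
        betas = np.broadcast_to(betas, vox.shape).astype(float).copy()
        if vox.size:
            effects[src] = (vox, betas)
    return effects


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Build a full synthetic cohort from one seeded generator."""
    rng = np.random.default_rng(config.rng_seed)
    grid = config.grid_shape
    V = config.n_voxels
    T = config.n_timepoints
    S = 2 * config.n_subjects_per_sex

    mask = ellipsoid_mask(grid)
    gm = gray_matter_mask(mask)
    flat_mask = mask.ravel()
    source_maps = generate_source_maps(config, rng)
    sex_effects = _default_sex_effects(config, source_maps, rng)

    # covariates (sexes interleaved so ids carry no group ordering)
    sexes = np.array(["F", "M"] * config.n_subjects_per_sex)
    age = rng.choice(_AGE_BINS, size=S)
    iq = rng.normal(_IQ_MEAN, _IQ_SD, size=S)
    scanner = rng.integers(0, _N_SCANNERS, size=S)
    log_motion = rng.normal(0.0, 0.2, size=S) + config.dvars_male_shift * (sexes == "M")
    motion_mult = np.exp(log_motion)

    cov_z = {
        "age": _standardize(age.astype(float)),
        "iq": _standardize(iq),
        "scanner": _standardize(scanner.astype(float)),
        "motion": _standardize(log_motion),
    }
    # each nonzero nuisance effect gets its own planted voxel pattern on a
    # network source's support
    cov_patterns: dict[str, tuple[int, np.ndarray]] = {}
    for k, name in enumerate(("age", "iq", "scanner", "motion")):
        size = float(config.covariate_effect_sizes.get(name, 0.0))
        if size != 0.0 and config.n_neural_sources:
            src = k % config.n_neural_sources
            support = np.flatnonzero(source_maps[src] != 0)
            vox = np.sort(rng.choice(support, size=min(20, support.size), replace=False))
            cov_patterns[name] = (src, vox)

    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    runs: list[BoldRun] = []
    subject_maps = np.empty((S, config.n_sources, V), dtype=np.float32)
    subject_tcs = np.empty((S, config.n_sources, T), dtype=np.float32)
    dvars_mean = np.empty(S)

    for s in range(S):
        A = source_maps.copy()
        if config.subject_map_sd > 0:
            for c in range(config.n_sources):
                field = ndimage.gaussian_filter(rng.standard_normal(grid), sigma=1.5)
                field = field.ravel() * flat_mask
                sd = field[flat_mask].std()
                if sd > 0:
                    A[c] += config.subject_map_sd * field / sd
        if sexes[s] == "F":
            for src, (vox, betas) in sex_effects.items():
                A[src, vox] += betas
        for name, (src, vox) in cov_patterns.items():
            size = float(config.covariate_effect_sizes[name])
            A[src, vox] += size * cov_z[name][s]
        A *= flat_mask

        tc = generate_timecourses(config, sexes[s], rng)
        sigma_s = config.noise_sd * motion_mult[s]
        X = tc.T @ A
        if sigma_s > 0:
            X = X + sigma_s * rng.standard_normal((T, V)) * flat_mask

        data = np.moveaxis(X.reshape(T, *grid), 0, -1).astype(np.float32)
        run = BoldRun(
            data=data,
            tr_seconds=config.tr_seconds,
            affine=affine,
            mask=mask,
            subject_id=f"sub{s:04d}",
        )
        runs.append(run)
        subject_maps[s] = A
        subject_tcs[s] = tc
        d = np.diff(X[:, flat_mask], axis=0)
        dvars_mean[s] = float(np.sqrt((d**2).mean(axis=1)).mean())

    covariates = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in runs],
            "sex": sexes,
            "age_bin": age,
            "iq": np.round(iq, 2),
            "scanner": scanner,
            "dvars": dvars_mean,
        }
    )
    truth = GroundTruth(
        config=config,
        mask=mask,
        gm_mask=gm,
        source_maps=source_maps,
        neural_indices=np.arange(config.n_neural_sources),
        noise_indices=np.arange(config.n_neural_sources, config.n_sources),
        sex_effects=sex_effects,
        subject_maps=subject_maps,
        subject_timecourses=subject_tcs,
    )
    return SyntheticCohort(runs=runs, covariates=covariates, truth=truth)


# ---------------------------------------------------------------------------
# association atlas

def generate_association_atlas(
    config: SimulationConfig,
    effect_truth: GroundTruth | np.ndarray,
    term_names: Sequence[str] = DEFAULT_TERMS,
    overlap_fraction: float = 0.5,
    include_planted_probability: float = 0.7,
    rng: np.random.Generator | None = None,
) -> SyntheticAssociationAtlas:
    """Synthetic per-term z-maps with known overlap against planted effects.

    Each term's active set is a union of random in-mask blobs plus, with
    probability ``include_planted_probability`` per term, a random
    ``overlap_fraction`` subset of the planted sex-effect voxels, so
    per-term overlaps with the true effects are nonzero but not total.
    ``truth_overlap`` is the exact set intersection of each active set
    with the planted voxels.
    """
    terms = list(term_names)
    if not terms:
        raise ValidationError("term list must be non-empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 7]))
    if isinstance(effect_truth, GroundTruth):
        planted = effect_truth.effect_voxels
    else:
        planted = np.unique(np.asarray(effect_truth, dtype=np.intp))

    mask = ellipsoid_mask(config.grid_shape)
    flat_mask_idx = np.flatnonzero(mask.ravel())
    maps: dict[str, np.ndarray] = {}
    overlap: dict[str, np.ndarray] = {}
    for term in terms:
        active = np.zeros(config.n_voxels, dtype=bool)
        for _ in range(rng.integers(2, 5)):
            center = np.unravel_index(rng.choice(flat_mask_idx), config.grid_shape)
            blob = _gaussian_blob(config.grid_shape, np.array(center), 1.0) * mask
            active |= (blob.ravel() > 0.3)
        if planted.size and rng.random() < include_planted_probability:
            n_take = max(1, int(round(overlap_fraction * planted.size)))
            take = rng.choice(planted, size=n_take, replace=False)
            active[take] = True
        z = np.zeros(config.n_voxels)
        z[active] = rng.uniform(2.0, 8.0, size=int(active.sum()))
        maps[term] = z.reshape(config.grid_shape)
        overlap[term] = np.intersect1d(np.flatnonzero(active), planted)
    return SyntheticAssociationAtlas(term_names=terms, maps=maps, truth_overlap=overlap)


# ---------------------------------------------------------------------------
# disk output

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort as NIfTI-1 runs + mask, TSV covariates, JSON truth."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for run in cohort.runs:
        nib.Nifti1Image(run.data, run.affine).to_filename(
            str(outdir / f"{run.subject_id}_bold.nii")
        )
    mask = cohort.truth.mask
    nib.Nifti1Image(mask.astype(np.uint8), cohort.runs[0].affine).to_filename(
        str(outdir / "mask.nii")
    )
    nib.Nifti1Image(
        cohort.truth.gm_mask.astype(np.uint8), cohort.runs[0].affine
    ).to_filename(str(outdir / "gm_mask.nii"))
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    truth = cohort.truth
    payload = {
        "grid_shape": list(truth.config.grid_shape),
        "neural_indices": truth.neural_indices.tolist(),
        "noise_indices": truth.noise_indices.tolist(),
        "sex_effects": {
            str(src): {"voxels": vox.tolist(), "betas": betas.tolist()}
            for src, (vox, betas) in truth.sex_effects.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2))


def write_atlas(atlas: SyntheticAssociationAtlas, outdir: str | Path, affine=None) -> None:
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    for term in atlas.term_names:
        safe = term.replace(" ", "_")
        nib.Nifti1Image(atlas.maps[term].astype(np.float32), affine).to_filename(
            str(outdir / f"association_{safe}.nii")
        )
    payload = {t: atlas.truth_overlap[t].tolist() for t in atlas.term_names}
    (outdir / "atlas_truth_overlap.json").write_text(json.dumps(payload, indent=2))
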