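"""Configuration objects for the synthetic cohort and the full pipeline.

The simulation emulates the study design the statistics were built for:
two sex groups scanned for ~6 minutes at TR = 3 s (124 volumes), a small
number of spatially sparse low-frequency network sources mixed with
artefactual high-frequency sources, covariate structure (age bin, estimated
IQ, scanner site, head motion), and additive sex effects of known sign and
magnitude planted at known voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

#: Default neurocognitive term battery for footprint mapping: nine functions
#: with robust evidence of sex-related performance differences plus seven
#: cognitive-control comparison terms.
DEFAULT_TERMS: tuple[str, ...] = (
    "visuospatial",
    "spatial",
    "verbal",
    "verbal fluency",
    "semantic memory",
    "rotation",
    "recognition memory",
    "reading",
    "arithmetic",
    "cognitive flexibility",
    "goal selection",
    "reaction time",
    "response selection",
    "selective attention",
    "sustained attention",
    "working memory",
)


@dataclass
class SimulationConfig:
    """Ground-truth generative settings for a synthetic cohort.

    Parameters
    ----------
    n_subjects_per_sex:
        Number of subjects in each sex group.
    n_timepoints:
        Volumes per run before equilibration trimming (default 124).
    tr_seconds:
        Repetition time in seconds (default 3.0).
    grid_shape:
        3D voxel grid; an ellipsoidal brain mask is inscribed in it.
    n_neural_sources, n_noise_sources:
        Counts of planted network sources (smooth in-mask blobs with
        low-frequency timecourses) and artefact sources (rim bands and
        speckle with high-frequency/flat spectra).
    sex_effect_voxels, sex_effect_betas:
        Per-source flat voxel indices (0-based, C order) and the signed
        additive shifts applied to female subject maps at those voxels.
        Positive beta therefore means an F > M effect.
    covariate_effect_sizes:
        Additive map-intensity loadings for the standardized nuisance
        covariates ``age``, ``iq``, ``scanner``, ``motion``. Zero by default
        so nuisance predictors are null unless explicitly planted.
    noise_sd:
        Standard deviation of the additive Gaussian measurement noise.
    source_amplitude:
        Peak intensity of each planted source map.
    subject_map_sd:
        Between-subject standard deviation of smooth source-map variability.
    dvars_male_shift:
        Shift (log scale) of the male motion multiplier, emulating the
        higher head motion observed in males.
    rng_seed:
        Seed for the single cohort-level generator; every sub-draw derives
        from it, so a fixed seed yields byte-identical cohorts.
    """

    n_subjects_per_sex: int = 20
    n_timepoints: int = 124
    tr_seconds: float = 3.0
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    n_neural_sources: int = 6
    n_noise_sources: int = 3
    sex_effect_voxels: Mapping[int, Sequence[int]] | None = None
    sex_effect_betas: Mapping[int, Sequence[float]] | None = None
    covariate_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.0, "iq": 0.0, "scanner": 0.0, "motion": 0.0}
    )
    noise_sd: float = 1.0
    source_amplitude: float = 2.0
    subject_map_sd: float = 0.1
    dvars_male_shift: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.validate()

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_sources(self) -> int:
        return self.n_neural_sources + self.n_noise_sources

    def validate(self) -> None:
        if self.n_subjects_per_sex < 1:
            raise ValidationError("n_subjects_per_sex must be >= 1")
        if self.n_timepoints < 8:
            raise ValidationError("n_timepoints must be >= 8")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValidationError("grid_shape must be 3 positive integers")
        if self.n_neural_sources < 0 or self.n_noise_sources < 0:
            raise ValidationError("source counts must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.sex_effect_voxels is not None:
            for src, vox in self.sex_effect_voxels.items():
                vox = np.asarray(vox)
                if vox.size and (vox.min() < 0 or vox.max() >= self.n_voxels):
                    raise ValidationError(
                        f"sex effect voxels for source {src} fall outside the grid"
                    )
                if not 0 <= src < self.n_sources:
                    raise ValidationError(f"sex effect source {src} out of range")
        if self.sex_effect_betas is not None:
            for src, betas in self.sex_effect_betas.items():
                if not np.all(np.isfinite(np.asarray(betas, dtype=float))):
                    raise ValidationError(f"betas for source {src} must be finite")
            if self.sex_effect_voxels is not None:
                for src in self.sex_effect_betas:
                    nb = len(self.sex_effect_betas[src])
                    nv = len(self.sex_effect_voxels.get(src, ()))
                    if nb not in (1, nv):
                        raise ValidationError(
                            f"source {src}: need one beta per voxel (or a scalar)"
                        )


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    ``model_orders`` pairs each ICA model order with its subject-level PCA
    dimension; study-scale defaults are {15: 20, 40: 50, 100: 110}.
    """

    model_orders: Mapping[int, int] = field(
        default_factory=lambda: {15: 20, 40: 50, 100: 110}
    )
    n_ica_runs: int = 10
    threshold_multiplier: float = 4.0
    fdr_level: float = 0.01
    falff_min: float = 2.0
    gm_overlap_min: float = 0.5
    alpha_keep: float = 0.01
    motion_match_alpha: float = 0.05
    correspondence_cutoff: float = 0.85
    n_trim: int = 4
    connectivity: int = 26
    terms: Sequence[str] = DEFAULT_TERMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_level < 1):
            raise ValidationError("fdr_level must lie in (0, 1)")
        for order, k in self.model_orders.items():
            if k < order:
                raise ValidationError(
                    f"PCA dimension {k} must be >= model order {order}"
                )
        if self.n_ica_runs < 1:
            raise ValidationError("n_ica_runs must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValidationError("connectivity must be one of 6, 18, 26")
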