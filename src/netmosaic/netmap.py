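"""Thresholded intrinsic-network spatial maps.

For each retained (neural) component, a voxelwise one-sample t-test over
the subject-specific maps summarizes how consistently each voxel loads on
the component, and the t-map is thresholded at mean + 4 standard
deviations (computed over in-mask t-values) to keep only the strongest,
most consistent coactivations. The surviving voxel set is the network
spatial map on which dimorphism is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["NetworkSpatialMap", "one_sample_tmap", "threshold_map", "assign_labels"]


@dataclass
class NetworkSpatialMap:
    network_id: int
    t_map: np.ndarray            # flat, length V
    voxels: np.ndarray           # sorted flat indices exceeding the threshold
    threshold: float
    label: str = ""
    empty_flagged: bool = False

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.size)


def one_sample_tmap(subject_maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t statistic over subjects.

    ``subject_maps`` is (n_subjects, V). Returns (t_map, zero_variance
    flags); zero-variance voxels get t = 0 so downstream thresholding
    stays finite.
    """
    m = np.asarray(subject_maps, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3:
        raise ValidationError("need subject maps from at least 3 subjects")
    n = m.shape[0]
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    flags = sd == 0
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~flags)
    return t, flags


def threshold_map(
    t_map: np.ndarray,
    mask: np.ndarray | None = None,
    network_id: int = 0,
    multiplier: float = 4.0,
) -> NetworkSpatialMap:
    """Retain voxels with t > mean + ``multiplier`` * sd.

    Mean and sd are computed over in-mask t-values (the whole map when no
    mask is given). A zero-spread map yields an empty, flagged network.
    """
    t = np.asarray(t_map, dtype=float).ravel()
    if mask is not None:
        in_mask = np.asarray(mask).ravel().astype(bool)
        if in_mask.shape != t.shape:
            raise ValidationError("mask and t-map sizes differ")
    else:
        in_mask = np.ones(t.shape, dtype=bool)
    vals = t[in_mask]
    if vals.size == 0 or not np.isfinite(vals).all():
        raise ValidationError("t-map must be finite on the mask")
    mu, sd = vals.mean(), vals.std()
    cut = mu + multiplier * sd
    if sd == 0:
        return NetworkSpatialMap(network_id, t, np.empty(0, dtype=np.intp), cut, empty_flagged=True)
    voxels = np.flatnonzero((t > cut) & in_mask)
    return NetworkSpatialMap(network_id, t, voxels, float(cut), empty_flagged=voxels.size == 0)


def assign_labels(
    maps: list[NetworkSpatialMap], label_table: dict[int, str] | None = None
) -> list[NetworkSpatialMap]:
    """Attach user-provided labels; unlabeled networks get 'IN<k>'."""
    table = dict(label_table or {})
    ids = [m.network_id for m in maps]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate network ids")
    for m in maps:
        m.label = table.get(m.network_id, f"IN{m.network_id}")
    return maps
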