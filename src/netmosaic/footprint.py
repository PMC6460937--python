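"""Mapping dimorphic voxels onto neurocognitive association-test maps.

Association test maps are meta-analytic z-maps, one per neurocognitive
term, giving the brain locations selectively activated by that function.
The footprint of sex-related effects for a term is the number of unique
dimorphic voxels — pooled across every network of one model, per effect
direction — that coincide with the term map's active voxels. Comparing
F > M and M > F footprints per term quantifies whose dimorphic territory
covers more of each cognitive map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, ValidationError

__all__ = [
    "AssociationMap",
    "EffectOverlap",
    "binarize_association_map",
    "overlap_voxels",
    "aggregate_unique",
    "footprint_table",
]


@dataclass
class AssociationMap:
    term: str
    z_map: np.ndarray              # 3D
    active: np.ndarray             # sorted flat voxel indices
    empty_flagged: bool = False


@dataclass
class EffectOverlap:
    term: str
    network_id: int
    direction: str
    voxels: np.ndarray             # sorted flat indices


def binarize_association_map(
    z_map: np.ndarray, term: str = "", rule: float | None = None
) -> AssociationMap:
    """Active set of a term map.

    Default rule: active iff z > 0 (the consumed maps are pre-thresholded,
    so any nonzero-positive voxel is an activation). Passing ``rule=c``
    applies a fixed threshold z > c instead. An all-inactive map yields an
    empty, flagged active set.
    """
    z = np.asarray(z_map, dtype=float)
    if z.ndim != 3:
        raise ValidationError("association map must be 3D")
    cut = 0.0 if rule is None else float(rule)
    active = np.flatnonzero(z.ravel() > cut)
    return AssociationMap(term, z, active, empty_flagged=active.size == 0)


def overlap_voxels(
    effect_voxels: np.ndarray,
    association: AssociationMap,
    grid_shape: tuple[int, int, int],
    network_id: int = 0,
    direction: str = "",
) -> EffectOverlap:
    """Voxels present in both an effect map and a term's active set."""
    if association.z_map.shape != tuple(grid_shape):
        raise GridMismatchError(
            f"association map grid {association.z_map.shape} != analysis grid "
            f"{tuple(grid_shape)}; resample the map upstream"
        )
    inter = np.intersect1d(
        np.asarray(effect_voxels, dtype=np.intp), association.active
    )
    return EffectOverlap(association.term, network_id, direction, inter)


def aggregate_unique(overlaps: list[EffectOverlap]) -> dict:
    """Per (term, direction): the union of overlap voxels across networks,
    duplicates removed. Directions are never merged."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for ov in overlaps:
        key = (ov.term, ov.direction)
        if key in out:
            out[key] = np.union1d(out[key], ov.voxels)
        else:
            out[key] = np.unique(np.asarray(ov.voxels, dtype=np.intp))
    return out


def footprint_table(
    unique_sets: dict, terms: list[str], f_label: str = "F>M", m_label: str = "M>F"
) -> pd.DataFrame:
    """Per-term footprint counts and the male-excess statistic.

    Columns: unique F > M count, unique M > F count, percent difference
    (M - F) / F * 100 (NaN-flagged when F = 0), and the relative
    proportions M / (M + F) and F / (M + F).
    """
    rows = []
    for term in terms:
        f_count = int(len(unique_sets.get((term, f_label), ())))
        m_count = int(len(unique_sets.get((term, m_label), ())))
        total = f_count + m_count
        rows.append(
            {
                "term": term,
                "f_count": f_count,
                "m_count": m_count,
                "pct_difference": (m_count - f_count) / f_count * 100.0
                if f_count > 0
                else float("nan"),
                "undefined": f_count == 0,
                "m_proportion": m_count / total if total else float("nan"),
                "f_proportion": f_count / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)
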