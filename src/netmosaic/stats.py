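"""Detection and quantification of directional sex effects in network maps.

The workflow per network: build a design matrix (sex coded F = 1 / M = 0,
so a positive sex coefficient is an F > M effect; age bin, estimated IQ,
scanner dummies and DVARS as nuisance predictors), reduce it by backward
elimination with multivariate F-tests (Lawley-Hotelling trace) on a
PCA-reduced response, then — when sex survives — run ordinary
least-squares at every voxel of the original maps, pool p-values across
all networks of one model order and control the false discovery rate by
Benjamini-Hochberg at q <= 0.01. Significant voxels are split by the sign
of the sex coefficient, grouped into connected clusters with an average
beta per cluster, and summarized as fractions of each network's territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .netmap import NetworkSpatialMap

__all__ = [
    "DesignMatrix",
    "ReducedModel",
    "ClusterEffect",
    "NetworkEffectSummary",
    "build_design",
    "lawley_hotelling_test",
    "mancova_reduce",
    "voxelwise_univariate",
    "fdr_correct",
    "split_directions",
    "connected_clusters",
    "network_fraction",
    "model_average_area",
]

F_GREATER = "F>M"
M_GREATER = "M>F"


@dataclass
class DesignMatrix:
    matrix: np.ndarray                    # n x q
    columns: list                         # column names
    groups: dict                          # predictor -> list of column indices

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ReducedModel:
    retained: list                        # predictors kept (never the intercept)
    pvalues: dict                         # predictor -> final multivariate p
    trace: list                           # (predictor, p) in elimination order
    sex_retained: bool
    response_dim: int


@dataclass
class ClusterEffect:
    network_id: int
    direction: str
    voxels: np.ndarray
    mean_beta: float


@dataclass
class NetworkEffectSummary:
    network_id: int
    total_voxels: int
    per_direction: dict = field(default_factory=dict)
    # direction -> {"count", "fraction", "mean_beta", "clusters"}


# ---------------------------------------------------------------------------
# design

def build_design(covariates: pd.DataFrame) -> DesignMatrix:
    """Design matrix from the covariate table.

    Sex is coded F = 1 / M = 0; age bin, IQ and DVARS are centered; the
    scanner factor is dummy-coded against its first level.
    """
    required = {"subject_id", "sex", "age_bin", "iq", "scanner", "dvars"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValidationError(f"covariates missing columns: {sorted(missing)}")
    if covariates[list(required)].isna().any().any():
        raise ValidationError("covariates contain missing values")
    sex = (covariates["sex"].to_numpy() == "F").astype(float)
    if sex.min() == sex.max():
        raise ValidationError("only one sex present; the sex column is constant")

    cols: list[np.ndarray] = [np.ones(len(covariates)), sex]
    names = ["intercept", "sex"]
    groups: dict[str, list[int]] = {"intercept": [0], "sex": [1]}
    for name in ("age_bin", "iq", "dvars"):
        x = covariates[name].to_numpy(float)
        cols.append(x - x.mean())
        groups[name] = [len(names)]
        names.append(name)
    levels = sorted(pd.unique(covariates["scanner"]))
    scanner_cols = []
    for lev in levels[1:]:
        cols.append((covariates["scanner"].to_numpy() == lev).astype(float))
        scanner_cols.append(len(names))
        names.append(f"scanner[{lev}]")
    if scanner_cols:
        groups["scanner"] = scanner_cols

    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = [
            names[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValidationError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(x, names, groups)


def _subset(design: DesignMatrix, predictors: list[str]) -> np.ndarray:
    idx = [j for p in predictors for j in design.groups[p]]
    return design.matrix[:, idx]


# ---------------------------------------------------------------------------
# multivariate testing

def lawley_hotelling_test(
    y: np.ndarray, x_full: np.ndarray, x_reduced: np.ndarray
) -> tuple[float, float]:
    """Lawley-Hotelling trace with F approximation for a nested comparison.

    ``y`` is n x p (responses), ``x_full`` contains the hypothesis columns
    that ``x_reduced`` lacks. Returns (trace, p_value).
    """
    n, p = y.shape
    q = x_full.shape[1] - x_reduced.shape[1]
    if q < 1:
        raise ValidationError("x_full must strictly contain x_reduced")

    def _rss(x: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return r.T @ r

    e_full = _rss(x_full)
    e_red = _rss(x_reduced)
    h = e_red - e_full
    ve = n - np.linalg.matrix_rank(x_full)
    if ve <= p + 1:
        raise ValidationError(
            f"too few error degrees of freedom (n={n}, p={p}, rank={n - ve})"
        )
    trace = float(np.trace(np.linalg.solve(e_full, h)))
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (ve - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = 2 * (s * nn + 1)
    f_stat = trace * 2 * (s * nn + 1) / (s * s * (2 * m + s + 1))
    return trace, float(sps.f.sf(f_stat, df1, df2))


def mancova_reduce(
    subject_maps: np.ndarray,
    design: DesignMatrix,
    alpha_keep: float = 0.01,
    variance_fraction: float = 0.9,
) -> ReducedModel:
    """Backward predictor elimination on a PCA-reduced multivariate response.

    The voxel dimension is reduced to the smallest number of principal
    components capturing ``variance_fraction`` of the variance, capped at
    n/10 (and at least 1). Nuisance predictors with the largest
    multivariate p are dropped one at a time until all remaining ones pass
    ``alpha_keep``; sex is then retained iff its own multivariate test in
    the final model passes — never forced either way.
    """
    y = np.asarray(subject_maps, dtype=float)
    n = y.shape[0]
    if n != design.n:
        raise ValidationError("subject maps and design row counts differ")
    yc = y - y.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(yc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValidationError("response has zero variance")
    cum = np.cumsum(var) / total
    d = int(np.searchsorted(cum, variance_fraction) + 1)
    d = max(1, min(d, max(n // 10, 1)))
    # keep response df small enough for the F approximation
    d = min(d, n - len(design.columns) - 2)
    if d < 1:
        raise ValidationError("too few subjects for the multivariate reduction")
    y_red = u[:, :d] * s[:d]

    nuisance = [p for p in design.groups if p not in ("intercept", "sex")]
    current = ["intercept", "sex"] + nuisance
    trace_log: list[tuple[str, float]] = []
    while True:
        pvals = {}
        for pred in [p for p in current if p not in ("intercept", "sex")]:
            x_red = _subset(design, [c for c in current if c != pred])
            _, pv = lawley_hotelling_test(y_red, _subset(design, current), x_red)
            pvals[pred] = pv
        if not pvals:
            break
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha_keep:
            break
        trace_log.append((worst, pvals[worst]))
        current.remove(worst)

    final_p: dict[str, float] = dict(pvals) if pvals else {}
    x_no_sex = _subset(design, [c for c in current if c != "sex"])
    _, sex_p = lawley_hotelling_test(y_red, _subset(design, current), x_no_sex)
    final_p["sex"] = sex_p
    sex_retained = sex_p < alpha_keep
    retained = [c for c in current if c != "intercept"]
    if not sex_retained:
        retained = [c for c in retained if c != "sex"]
    return ReducedModel(retained, final_p, trace_log, sex_retained, d)


# ---------------------------------------------------------------------------
# voxelwise testing

def voxelwise_univariate(
    subject_maps: np.ndarray,
    design: DesignMatrix,
    reduced: ReducedModel | None = None,
    network_id: int = 0,
    voxel_indices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-voxel OLS of map value on the full original design.

    Returns a table (network, voxel, beta, t, p) for the sex coefficient;
    nuisance effects are partialled out by inclusion in the model. When a
    reduced model is supplied and sex was not retained the table is empty.
    """
    cols = ["network", "voxel", "beta", "t", "p"]
    if reduced is not None and not reduced.sex_retained:
        return pd.DataFrame(columns=cols)
    y = np.asarray(subject_maps, dtype=float)
    x = design.matrix
    n, q = x.shape
    if y.shape[0] != n:
        raise ValidationError("subject maps and design row counts differ")
    if voxel_indices is None:
        voxel_indices = np.arange(y.shape[1])
    sex_col = design.groups["sex"][0]

    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ y                      # q x V
    resid = y - x @ beta
    dof = n - np.linalg.matrix_rank(x)
    sigma2 = (resid**2).sum(axis=0) / dof
    b = beta[sex_col]
    # voxels with (numerically) zero residual variance are exact fits:
    # a nonzero sex beta there is a perfect effect (p = 0), a zero beta a
    # perfect non-effect (p = 1); without the tolerance, machine-precision
    # residuals would turn noise-free data into garbage t ratios
    scale = float(np.abs(y).max()) + 1.0
    var_tol = (1e-8 * scale) ** 2
    normal = sigma2 > var_tol
    se = np.sqrt(np.clip(sigma2 * xtx_inv[sex_col, sex_col], 0, None))
    t = np.zeros_like(b)
    np.divide(b, se, out=t, where=normal & (se > 0))
    p = np.where(normal, 2 * sps.t.sf(np.abs(t), dof), 1.0)
    exact_hit = ~normal & (np.abs(b) > 1e-6 * scale)
    t[exact_hit] = np.sign(b[exact_hit]) * np.inf
    p[exact_hit] = 0.0
    return pd.DataFrame(
        {
            "network": network_id,
            "voxel": np.asarray(voxel_indices),
            "beta": b,
            "t": t,
            "p": p,
        }
    )


def fdr_correct(effects: pd.DataFrame, q_level: float = 0.01) -> pd.DataFrame:
    """Benjamini-Hochberg over the pooled p-values of all networks in one
    model order; adds ``q`` (adjusted p) and ``significant`` columns."""
    out = effects.copy()
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    p = out["p"].to_numpy(float)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    out["q"] = q
    out["significant"] = q <= q_level
    return out


def split_directions(effects: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition significant effects by the sign of the sex beta."""
    if len(effects) == 0:
        empty = effects.copy()
        return empty, empty.copy()
    if "significant" in effects.columns:
        sig = effects[effects["significant"].astype(bool)]
    else:
        sig = effects
    return (
        sig[sig["beta"] > 0].reset_index(drop=True),
        sig[sig["beta"] < 0].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# clusters and fractions

_STRUCTURE = {6: 1, 18: 2, 26: 3}


def connected_clusters(
    voxels: np.ndarray,
    betas: np.ndarray,
    grid_shape: tuple[int, int, int],
    connectivity: int = 26,
    network_id: int = 0,
    direction: str = "",
) -> list[ClusterEffect]:
    """Connected-component labeling of a significant voxel set.

    ``voxels`` are flat indices into ``grid_shape`` (C order); clusters use
    6-, 18- or 26-connectivity, and each carries the arithmetic mean of its
    member betas.
    """
    if connectivity not in _STRUCTURE:
        raise ValidationError("connectivity must be one of 6, 18, 26")
    voxels = np.asarray(voxels, dtype=np.intp)
    betas = np.asarray(betas, dtype=float)
    if voxels.size == 0:
        return []
    vol = np.zeros(grid_shape, dtype=bool)
    vol.ravel()[voxels] = True
    structure = ndimage.generate_binary_structure(3, _STRUCTURE[connectivity])
    labels, n_lab = ndimage.label(vol, structure=structure)
    flat_labels = labels.ravel()[voxels]
    beta_by_voxel = dict(zip(voxels.tolist(), betas.tolist()))
    out = []
    for lab in range(1, n_lab + 1):
        members = np.sort(voxels[flat_labels == lab])
        mean_beta = float(np.mean([beta_by_voxel[v] for v in members]))
        out.append(ClusterEffect(network_id, direction, members, mean_beta))
    return out


def network_fraction(
    network_map: NetworkSpatialMap,
    effects: pd.DataFrame,
    grid_shape: tuple[int, int, int],
    connectivity: int = 26,
) -> NetworkEffectSummary:
    """Per-direction significant-voxel counts, network fractions, clusters
    and average effect sizes for one network."""
    total = network_map.n_voxels
    if total == 0:
        raise ValidationError(f"network {network_map.network_id} map is empty")
    f_gt, m_gt = split_directions(effects)
    summary = NetworkEffectSummary(network_map.network_id, total)
    for direction, sub in ((F_GREATER, f_gt), (M_GREATER, m_gt)):
        clusters = connected_clusters(
            sub["voxel"].to_numpy(),
            sub["beta"].to_numpy(),
            grid_shape,
            connectivity,
            network_map.network_id,
            direction,
        )
        summary.per_direction[direction] = {
            "count": len(sub),
            "fraction": len(sub) / total,
            "mean_beta": float(sub["beta"].mean()) if len(sub) else 0.0,
            "clusters": clusters,
        }
    return summary


def model_average_area(summaries: list[NetworkEffectSummary]) -> dict:
    """Model-level average area: the arithmetic mean over networks of each
    direction's fraction of network territory."""
    out = {}
    for direction in (F_GREATER, M_GREATER):
        fracs = [s.per_direction[direction]["fraction"] for s in summaries]
        out[direction] = float(np.mean(fracs)) if fracs else 0.0
    return out
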