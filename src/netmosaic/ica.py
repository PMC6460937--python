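"""Multilevel group spatial ICA.

The decomposition follows the temporal-concatenation group ICA recipe:
per-subject PCA reduction of the pre-whitened runs, a second PCA on the
temporal concatenation, Infomax unmixing repeated from random
initializations, stability clustering of the pooled runs with centrotype
aggregation, and guided back-reconstruction of subject-specific spatial
maps and timecourses against the stabilized group maps. Component maps and
timecourses are z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import skew

from .exceptions import ValidationError
from .qc import BoldRun

__all__ = [
    "PCAReduction",
    "GroupDecomposition",
    "SubjectDecomposition",
    "prewhiten",
    "reduce_subject",
    "concatenate_and_reduce",
    "infomax_ica",
    "icasso_stabilize",
    "dual_regression",
    "gig_backreconstruct",
    "zscore_rows",
    "match_components",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class PCAReduction:
    basis: np.ndarray              # T x k, orthonormal columns
    eigenvalues: np.ndarray        # all eigenvalues, descending
    retained_variance: float       # fraction in the first k


@dataclass
class GroupDecomposition:
    model_order: int
    group_maps: np.ndarray         # C x V, z-scored per component
    stability_index: np.ndarray    # C, in [0, 1]
    cluster_assignments: np.ndarray  # (R * C,) cluster id per pooled component
    centrotype_members: np.ndarray   # C, pooled index of each centrotype
    group_timecourses: dict = field(default_factory=dict)  # subject_id -> C x T


@dataclass
class SubjectDecomposition:
    subject_id: str
    subject_maps: np.ndarray       # C x V, z-scored
    subject_timecourses: np.ndarray  # C x T, z-scored
    fallback_components: np.ndarray  # bool per component (dual-regression fallback)


# ---------------------------------------------------------------------------
# helpers

def zscore_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row; zero-variance rows are left as zeros and flagged."""
    m = np.asarray(m, dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    flags = (sd[:, 0] == 0)
    out = np.where(sd > 0, (m - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out, flags


def prewhiten(run: BoldRun | np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """T x V matrix with each voxel timecourse demeaned and unit variance.

    Zero-variance voxels stay zero. Accepts a :class:`BoldRun` (uses its
    mask) or an already-extracted T x V matrix.
    """
    if isinstance(run, BoldRun):
        x = run.in_mask_matrix().astype(float)
    else:
        x = np.asarray(run, dtype=float)
        if mask is not None:
            x = x[..., np.asarray(mask).ravel()]
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    return np.where(sd > 0, x / np.where(sd > 0, sd, 1.0), 0.0)


def match_components(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hungarian matching of component rows on absolute Pearson correlation.

    Returns ``(rows_of_a, rows_of_b, |r|)`` for the optimal pairing.
    """
    az, _ = zscore_rows(a)
    bz, _ = zscore_rows(b)
    corr = np.abs(az @ bz.T) / a.shape[1]
    ri, ci = linear_sum_assignment(-corr)
    return ri, ci, corr[ri, ci]


# ---------------------------------------------------------------------------
# PCA reductions

def reduce_subject(
    run: BoldRun | np.ndarray, k: int, mask: np.ndarray | None = None
) -> tuple[PCAReduction, np.ndarray]:
    """Subject-level temporal PCA of the pre-whitened run.

    Returns the reduction (orthonormal T x k temporal basis, retained
    variance) and the reduced k x V data.
    """
    x = prewhiten(run, mask)
    t, v = x.shape
    if not 1 <= k <= min(t, v):
        raise ValidationError(f"k={k} must lie in [1, min(T={t}, V={v})]")
    cov = x @ x.T / v
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    retained = float(evals[:k].sum() / total) if total > 0 else 0.0
    basis = evecs[:, :k]
    return PCAReduction(basis, evals, retained), basis.T @ x


def concatenate_and_reduce(
    reduced_subjects: list[np.ndarray], model_order: int
) -> dict:
    """Second-level PCA on the temporal concatenation of reduced subjects.

    Returns the whitened group matrix (model_order x V, rows decorrelated
    with unit variance) together with the unwhitened projection and the
    concatenation bookkeeping.
    """
    shapes = {m.shape for m in reduced_subjects}
    if len({s[1] for s in shapes}) != 1 or len({s[0] for s in shapes}) != 1:
        raise ValidationError("all subjects must share k and V")
    z = np.vstack(reduced_subjects)               # (k*S) x V
    total_dim, v = z.shape
    if not 1 <= model_order <= total_dim:
        raise ValidationError(
            f"model_order={model_order} exceeds total reduced dimension {total_dim}"
        )
    z = z - z.mean(axis=1, keepdims=True)
    cov = z @ z.T / v
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    basis = evecs[:, :model_order]                # (k*S) x C, orthonormal
    projected = basis.T @ z                       # C x V
    scale = np.sqrt(np.clip(evals[:model_order], 1e-12, None))
    whitened = projected / scale[:, None]
    total = evals.sum()
    return {
        "whitened": whitened,
        "projected": projected,
        "basis": basis,
        "eigenvalues": evals,
        "retained_variance": float(evals[:model_order].sum() / total) if total > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# Infomax

def _sign_align(maps: np.ndarray) -> np.ndarray:
    """Flip component signs so each map has positive skew."""
    s = skew(maps, axis=1)
    flips = np.where(s < 0, -1.0, 1.0)
    return maps * flips[:, None]


def infomax_ica(
    group_matrix: np.ndarray,
    seed: int | np.random.Generator = 0,
    learning_rate: float = 1e-2,
    max_iter: int = 500,
    tol: float = 1e-6,
    block_size: int | None = None,
) -> dict:
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    ``group_matrix`` must be whitened, shape C x V (components x voxel
    samples). The learning rate is annealed whenever the weights blow up.
    Non-convergence returns the best iterate with ``converged=False`` rather
    than raising. Component maps are scaled to unit variance and
    sign-aligned to positive skew.
    """
    x = np.asarray(group_matrix, dtype=float)
    c, v = x.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if block_size is None:
        block_size = int(min(max(np.floor(np.sqrt(v / 3.0)), 8), 512))
    w = np.eye(c) + 0.05 * rng.standard_normal((c, c))
    lr = learning_rate
    eye = np.eye(c)
    converged = False
    n_iter = 0
    prev_delta_w: np.ndarray | None = None
    for n_iter in range(1, max_iter + 1):
        w_old = w.copy()
        perm = rng.permutation(v)
        blew_up = False
        for start in range(0, v, block_size):
            idx = perm[start : start + block_size]
            u = w @ x[:, idx]
            y = 1.0 / (1.0 + np.exp(-u))
            grad = (len(idx) * eye + (1.0 - 2.0 * y) @ u.T) @ w
            w = w + (lr / len(idx)) * grad
            if not np.isfinite(w).all() or np.abs(w).max() > 1e8:
                blew_up = True
                break
        if blew_up:
            lr *= 0.5
            w = np.eye(c) + 0.05 * rng.standard_normal((c, c))
            prev_delta_w = None
            continue
        delta_w = w - w_old
        # anneal when successive updates point >60 degrees apart
        if prev_delta_w is not None:
            num = float((delta_w * prev_delta_w).sum())
            den = np.linalg.norm(delta_w) * np.linalg.norm(prev_delta_w)
            if den > 0 and num / den < 0.5:
                lr *= 0.9
        prev_delta_w = delta_w
        delta = np.abs(delta_w).max() / max(np.abs(w).max(), 1e-12)
        if delta < tol:
            converged = True
            break
    maps = w @ x
    sd = maps.std(axis=1, keepdims=True)
    maps = np.where(sd > 0, maps / np.where(sd > 0, sd, 1.0), 0.0)
    maps = _sign_align(maps)
    return {"unmixing": w, "maps": maps, "converged": converged, "n_iter": n_iter}


# ---------------------------------------------------------------------------
# ICASSO stabilization

def icasso_stabilize(run_maps: list[np.ndarray]) -> GroupDecomposition:
    """Cluster pooled components from repeated ICA runs and keep centrotypes.

    Components from ``R`` runs are pooled, clustered agglomeratively
    (average linkage) on dissimilarity ``1 - |r|``, and cut into
    ``model_order`` clusters. Each cluster is represented by its centrotype
    (the member with the largest summed intra-cluster similarity). The
    stability index is mean intra-cluster minus mean extra-cluster
    similarity, clipped to [0, 1].
    """
    if len(run_maps) < 2:
        raise ValidationError("need at least 2 ICA runs to stabilize")
    orders = {m.shape[0] for m in run_maps}
    if len(orders) != 1:
        raise ValidationError("all runs must share the model order")
    c = orders.pop()
    pooled = np.vstack(run_maps)                   # (R*C) x V
    r_runs = len(run_maps)
    pz, _ = zscore_rows(pooled)
    sim = np.abs(pz @ pz.T) / pooled.shape[1]
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    tree = linkage(dist, method="average")

    # cut at exactly C clusters when possible, but a stray run can pull two
    # genuine clusters together at that cut; in that case cut finer and keep
    # the C best-populated clusters (outlier components form tiny clusters)
    min_size = max(2, r_runs // 2)
    chosen_labels = None
    for k in range(c, pooled.shape[0] + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        uniq, sizes = np.unique(labels, return_counts=True)
        if (sizes >= min_size).sum() >= c or k == pooled.shape[0]:
            order = np.argsort(-sizes, kind="stable")
            chosen = uniq[order[:c]]
            chosen_labels = (labels, chosen)
            break
    labels, chosen = chosen_labels

    maps = np.empty((c, pooled.shape[1]))
    stability = np.empty(c)
    members = np.empty(c, dtype=int)
    for k, lab in enumerate(chosen):
        inside = np.flatnonzero(labels == lab)
        outside = np.flatnonzero(labels != lab)
        sub = sim[np.ix_(inside, inside)]
        centro = inside[np.argmax(sub.sum(axis=1))]
        members[k] = centro
        maps[k] = pooled[centro]
        if len(inside) > 1:
            intra = (sub.sum() - len(inside)) / (len(inside) * (len(inside) - 1))
        else:
            intra = 1.0
        extra = sim[np.ix_(inside, outside)].mean() if len(outside) else 0.0
        stability[k] = np.clip(intra - extra, 0.0, 1.0)

    order = np.argsort(-stability, kind="stable")
    zmaps, _ = zscore_rows(_sign_align(maps[order]))
    return GroupDecomposition(
        model_order=c,
        group_maps=zmaps,
        stability_index=stability[order],
        cluster_assignments=labels,
        centrotype_members=members[order],
    )


# ---------------------------------------------------------------------------
# back-reconstruction

def dual_regression(
    x: np.ndarray, group_maps: np.ndarray, normalize_timecourses: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage least squares: spatial then temporal regression.

    ``x`` is the subject's T x V matrix, ``group_maps`` C x V. Returns
    ``(subject_maps C x V, timecourses C x T)`` in the data's units.
    With ``normalize_timecourses`` the stage-1 timecourses are scaled to
    unit variance before stage 2, which puts the subject maps on the
    data's intensity scale (useful when map effect sizes matter).
    """
    g = np.asarray(group_maps, dtype=float)
    tc, *_ = np.linalg.lstsq(g.T, x.T, rcond=None)       # C x T
    if normalize_timecourses:
        sd = tc.std(axis=1, keepdims=True)
        tc = np.where(sd > 0, tc / np.where(sd > 0, sd, 1.0), tc)
    maps, *_ = np.linalg.lstsq(tc.T, x, rcond=None)      # C x V
    return maps, tc


def _ica_with_reference(
    basis: np.ndarray,
    reference: np.ndarray,
    lambda_weight: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, bool]:
    """One-unit fixed-point ICA steered toward a reference map.

    ``basis`` is a spatially whitened k x V matrix (rows unit variance).
    Maximizes a log-cosh negentropy contrast plus ``lambda_weight`` times
    the correlation with the (z-scored) reference, under a unit-norm
    weight constraint. Returns the weight vector and a convergence flag.
    """
    v = basis.shape[1]
    rho = basis @ reference / v            # correlation of each basis row w/ ref
    nrm = np.linalg.norm(rho)
    w = rho / nrm if nrm > 0 else np.full(basis.shape[0], 1.0 / np.sqrt(basis.shape[0]))
    for _ in range(max_iter):
        m = w @ basis
        g = np.tanh(m)
        gprime = 1.0 - g**2
        w_new = basis @ g / v - gprime.mean() * w + lambda_weight * rho
        n = np.linalg.norm(w_new)
        if n == 0:
            return w, False
        w_new /= n
        if abs(1.0 - abs(w_new @ w)) < tol:
            return w_new, True
        w = w_new
    return w, False


def gig_backreconstruct(
    run: BoldRun | np.ndarray,
    group_maps: np.ndarray,
    lambda_weight: float = 1.0,
    mask: np.ndarray | None = None,
    subject_id: str | None = None,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> SubjectDecomposition:
    """Group-information-guided estimation of subject maps and timecourses.

    For each group component the subject map is the unit-variance linear
    combination of the subject's whitened spatial principal components that
    maximizes negentropy plus ``lambda_weight`` times correlation with the
    group reference. Components that fail to converge fall back to the
    dual-regression estimate and are flagged. The subject timecourses are
    the least-squares projection of the run onto the estimated maps; both
    outputs are z-scored.

    The run is demeaned per voxel but not variance-normalized: guided
    estimation must reproduce the generating maps exactly on noiseless
    data, which per-voxel rescaling would distort.
    """
    if isinstance(run, BoldRun):
        x = run.in_mask_matrix().astype(float)
    else:
        x = np.asarray(run, dtype=float)
        if mask is not None:
            x = x[..., np.asarray(mask).ravel()]
    x = x - x.mean(axis=0, keepdims=True)
    sid = subject_id or (run.subject_id if isinstance(run, BoldRun) else "")
    c, v = np.asarray(group_maps).shape
    if x.shape[1] != v:
        raise ValidationError("run and group maps must share the voxel grid")
    refs, _ = zscore_rows(group_maps)

    # spatially whitened subject basis via SVD, k = model order
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(c, int((s > 1e-10 * s[0]).sum()))
    basis = vt[:k] * np.sqrt(v)                    # rows ~ unit variance
    dr_maps, _ = dual_regression(x, refs)

    maps = np.empty((c, v))
    fallback = np.zeros(c, dtype=bool)
    for i in range(c):
        w, ok = _ica_with_reference(basis, refs[i], lambda_weight, max_iter, tol)
        if ok:
            m = w @ basis
            if m @ refs[i] < 0:
                m = -m
            maps[i] = m
        else:
            maps[i] = dr_maps[i]
            fallback[i] = True

    tcs, *_ = np.linalg.lstsq(maps.T, x.T, rcond=None)   # C x T
    zmaps, _ = zscore_rows(maps)
    ztcs, _ = zscore_rows(tcs)
    return SubjectDecomposition(sid, zmaps, ztcs, fallback)
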