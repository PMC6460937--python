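"""Group ICA chain: PCA reductions, Infomax separation, stability
clustering, and guided back-reconstruction against a dual-regression
oracle implemented independently in this module."""

import numpy as np
import pytest

from netmosaic.config import SimulationConfig
from netmosaic.cohort import generate_cohort
from netmosaic.exceptions import ValidationError
from netmosaic.ica import (
    concatenate_and_reduce,
    gig_backreconstruct,
    icasso_stabilize,
    infomax_ica,
    match_components,
    prewhiten,
    reduce_subject,
    zscore_rows,
)


def _oracle_dual_regression(x, group_maps):
    """Independent two-stage least-squares oracle (spatial then temporal),
    written directly from the definition."""
    tc = np.linalg.pinv(group_maps.T) @ x.T          # C x T
    maps = np.linalg.pinv(tc.T) @ x                  # C x V
    return maps, tc


class TestReduceSubject:
    def test_exact_rank_two_data_fully_retained(self, rng):
        t, v = 30, 500
        basis = rng.normal(size=(t, 2))
        x = basis @ rng.normal(size=(2, v))
        red, data = reduce_subject(x, 2)
        assert red.retained_variance == pytest.approx(1.0, abs=1e-9)
        assert data.shape == (2, v)

    def test_isotropic_noise_first_component_fraction(self, rng):
        # for T << V the top eigenvalue fraction approaches 1/min(T, V)
        t, v = 20, 4000
        red, _ = reduce_subject(rng.normal(size=(t, v)), 1)
        assert red.retained_variance == pytest.approx(1.0 / t, rel=0.2)

    def test_basis_orthonormal(self, rng):
        red, _ = reduce_subject(rng.normal(size=(25, 300)), 10)
        assert np.allclose(red.basis.T @ red.basis, np.eye(10), atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValidationError):
            reduce_subject(rng.normal(size=(10, 50)), 11)


class TestConcatenateAndReduce:
    def test_single_subject_identity_like(self, rng):
        _, y = reduce_subject(rng.normal(size=(20, 400)), 5)
        out = concatenate_and_reduce([y], 5)
        assert out["retained_variance"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_subject_spans_same_subspace(self, rng):
        _, y = reduce_subject(rng.normal(size=(20, 400)), 5)
        one = concatenate_and_reduce([y], 5)["projected"]
        two = concatenate_and_reduce([y, y], 5)["projected"]
        # principal angles between the two row spaces are ~0
        qa, _ = np.linalg.qr(one.T)
        qb, _ = np.linalg.qr(two.T)
        angles = np.linalg.svd(qa.T @ qb, compute_uv=False)
        assert np.allclose(angles, 1.0, atol=1e-8)

    def test_group_basis_orthonormal(self, rng):
        ys = [reduce_subject(rng.normal(size=(20, 400)), 5)[1] for _ in range(3)]
        out = concatenate_and_reduce(ys, 6)
        assert np.allclose(out["basis"].T @ out["basis"], np.eye(6), atol=1e-8)

    def test_model_order_too_large_rejected(self, rng):
        _, y = reduce_subject(rng.normal(size=(20, 400)), 5)
        with pytest.raises(ValidationError):
            concatenate_and_reduce([y], 6)


def _whiten(x):
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    return (evecs / np.sqrt(evals)).T @ x


class TestInfomax:
    def test_recovers_planted_super_gaussian_sources(self, rng):
        v = 5000
        sources = np.vstack([rng.uniform(-1, 1, v), rng.laplace(0, 1, v)])
        mixed = _whiten(np.array([[1.0, 0.6], [0.4, 1.0]]) @ sources)
        res = infomax_ica(mixed, seed=0)
        _, _, rvals = match_components(sources, res["maps"])
        assert (rvals >= 0.95).all()

    def test_already_unmixed_gives_signed_permutation(self, rng):
        v = 5000
        sources = _whiten(np.vstack([rng.laplace(size=v), rng.laplace(size=v)]))
        res = infomax_ica(sources, seed=1)
        w = res["unmixing"]
        # each row/column dominated by a single entry
        mags = np.abs(w) / np.abs(w).max(axis=1, keepdims=True)
        assert ((mags > 0.9).sum(axis=1) == 1).all()

    def test_two_seeds_agree_on_separated_sources(self, rng):
        v = 5000
        sources = np.vstack(
            [rng.laplace(size=v), rng.uniform(-2, 2, v), rng.laplace(size=v) ** 3]
        )
        mixed = _whiten(rng.normal(size=(3, 3)) @ sources)
        a = infomax_ica(mixed, seed=10)["maps"]
        b = infomax_ica(mixed, seed=20)["maps"]
        _, _, rvals = match_components(a, b)
        assert (rvals >= 0.95).all()


class TestIcasso:
    def test_identical_runs_fully_stable(self, rng):
        # intra-cluster similarity is exactly 1; the index only falls short
        # of 1.0 by the small chance similarity between distinct components
        maps = rng.normal(size=(4, 600))
        dec = icasso_stabilize([maps] * 5)
        assert (dec.stability_index > 0.9).all()
        _, _, rvals = match_components(maps, dec.group_maps)
        assert np.allclose(rvals, 1.0, atol=1e-12)

    def test_centrotype_matches_consistent_runs_despite_outlier(self, rng):
        base = rng.normal(size=(4, 600))
        runs = [base + 0.01 * rng.normal(size=base.shape) for _ in range(9)]
        runs.append(rng.normal(size=base.shape))  # one random run
        dec = icasso_stabilize(runs)
        _, _, rvals = match_components(base, dec.group_maps)
        assert (np.sort(rvals)[::-1][:4] >= 0.99).all()

    def test_invariant_to_run_order(self, rng):
        runs = [rng.normal(size=(3, 500)) + i for i in range(4)]
        a = icasso_stabilize(runs)
        b = icasso_stabilize(runs[::-1])
        _, _, rvals = match_components(a.group_maps, b.group_maps)
        assert np.allclose(np.sort(a.stability_index), np.sort(b.stability_index))
        assert np.allclose(rvals, 1.0, atol=1e-9)

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValidationError):
            icasso_stabilize([rng.normal(size=(3, 100))])


class TestZscore:
    def test_zscore_and_idempotence(self, rng):
        m = 5.0 + 2.0 * rng.normal(size=(3, 200))
        z, flags = zscore_rows(m)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)
        assert not flags.any()
        z2, _ = zscore_rows(z)
        assert np.allclose(z, z2)

    def test_zero_variance_row_flagged_and_zeroed(self):
        m = np.vstack([np.zeros(50), np.arange(50.0)])
        z, flags = zscore_rows(m)
        assert flags[0] and not flags[1]
        assert (z[0] == 0).all()


class TestGigBackreconstruction:
    def test_self_consistency_on_exact_group_data(self, rng):
        c, v, t = 3, 2000, 60
        maps, _ = zscore_rows(rng.laplace(size=(c, v)))
        tcs = rng.normal(size=(c, t))
        x = tcs.T @ maps
        sd = gig_backreconstruct(x, maps, subject_id="s")
        for i in range(c):
            assert abs(np.corrcoef(sd.subject_maps[i], maps[i])[0, 1]) >= 0.99

    def test_matches_dual_regression_oracle_on_cohort(self, tiny_cohort):
        truth = tiny_cohort.truth
        mask_idx = np.flatnonzero(truth.mask.ravel())
        refs, _ = zscore_rows(truth.source_maps[:, mask_idx])
        rs = []
        for run in tiny_cohort.runs[:4]:
            x = prewhiten(run)
            sd = gig_backreconstruct(x, refs)
            dr_maps, _ = _oracle_dual_regression(x, refs)
            drz, _ = zscore_rows(dr_maps)
            for i in range(refs.shape[0]):
                rs.append(abs(np.corrcoef(sd.subject_maps[i], drz[i])[0, 1]))
        assert np.median(rs) >= 0.8

    def test_subject_specific_deviation_recovered(self, rng):
        """When a subject's map deviates from the group map, the guided
        estimate lands closer to the subject's truth than the group map
        does, for most components and seeds."""
        wins = total = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            c, v, t = 3, 1500, 80
            group, _ = zscore_rows(r.laplace(size=(c, v)))
            subj_true = group + 0.35 * r.laplace(size=(c, v))
            subj_true, _ = zscore_rows(subj_true)
            x = r.normal(size=(c, t)).T @ subj_true + 0.3 * r.normal(size=(t, v))
            sd = gig_backreconstruct(x, group)
            for i in range(c):
                r_est = abs(np.corrcoef(sd.subject_maps[i], subj_true[i])[0, 1])
                r_grp = abs(np.corrcoef(group[i], subj_true[i])[0, 1])
                wins += r_est > r_grp
                total += 1
        assert wins / total >= 0.8

    def test_timecourses_explain_subject_better_than_group_average(self, tiny_cohort):
        """Back-projection consistency: subject map x subject timecourse
        reconstructs a subject's data better than the group-mean pattern."""
        truth = tiny_cohort.truth
        mask_idx = np.flatnonzero(truth.mask.ravel())
        refs, _ = zscore_rows(truth.source_maps[:, mask_idx])
        gains = []
        group_tcs = []
        for run in tiny_cohort.runs:
            x = prewhiten(run)
            _, tc = _oracle_dual_regression(x, refs)
            group_tcs.append(tc)
        mean_tc = np.mean(group_tcs, axis=0)
        for run, tc in zip(tiny_cohort.runs, group_tcs):
            x = prewhiten(run)
            sd = gig_backreconstruct(x, refs)
            maps_est, tc_est = _oracle_dual_regression(x, refs)
            own = np.linalg.norm(x - tc_est.T @ maps_est)
            grp = np.linalg.norm(x - mean_tc.T @ refs)
            gains.append(grp - own)
        assert np.mean(gains) > 0
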