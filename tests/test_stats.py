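"""Design construction, multivariate reduction, voxelwise sex effects,
FDR, clusters and network fractions — with independent oracles (statsmodels
MANOVA, brute-force BH step-up, BFS flood fill)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netmosaic.exceptions import ValidationError
from netmosaic.netmap import threshold_map
from oracles import bh_brute_force, clusters_as_sets, flood_fill_oracle

from netmosaic.stats import (
    build_design,
    connected_clusters,
    fdr_correct,
    lawley_hotelling_test,
    mancova_reduce,
    model_average_area,
    network_fraction,
    split_directions,
    voxelwise_univariate,
)


def _covariates(n, rng, sexes=None):
    if sexes is None:
        sexes = np.where(np.arange(n) % 2 == 0, "F", "M")
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "sex": sexes,
            "age_bin": rng.choice([19, 21, 23, 25], size=n),
            "iq": rng.normal(114, 8, size=n),
            "scanner": rng.integers(0, 5, size=n),
            "dvars": rng.lognormal(0, 0.2, size=n),
        }
    )


class TestDesign:
    def test_five_scanners_give_four_dummies(self, rng):
        cov = _covariates(40, rng)
        cov["scanner"] = np.arange(40) % 5
        design = build_design(cov)
        assert len(design.groups["scanner"]) == 4

    def test_single_sex_rejected(self, rng):
        cov = _covariates(20, rng, sexes=np.array(["F"] * 20))
        with pytest.raises(ValidationError):
            build_design(cov)

    def test_continuous_columns_centered(self, rng):
        design = build_design(_covariates(30, rng))
        j = design.groups["iq"][0]
        assert abs(design.matrix[:, j].sum()) < 1e-10

    def test_sex_coding_female_positive(self, rng):
        cov = _covariates(10, rng)
        design = build_design(cov)
        j = design.groups["sex"][0]
        assert np.array_equal(design.matrix[:, j], (cov["sex"] == "F").astype(float))

    def test_collinear_column_named(self, rng):
        cov = _covariates(20, rng)
        cov["dvars"] = cov["iq"]  # perfectly collinear after centering
        with pytest.raises(ValidationError, match="collinear"):
            build_design(cov)


class TestLawleyHotelling:
    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        n, p = 60, 3
        x = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=(n, p))
        y[:, 0] += 0.8 * x[:, 1]
        trace, pval = lawley_hotelling_test(y, x, x[:, [0, 2]])
        mv = MANOVA(endog=y, exog=x)
        res = mv.mv_test(hypotheses=[("x1", np.array([[0.0, 1.0, 0.0]]), None)])
        table = res.results["x1"]["stat"]
        sm_value = float(table.loc["Hotelling-Lawley trace", "Value"])
        sm_p = float(table.loc["Hotelling-Lawley trace", "Pr > F"])
        assert trace == pytest.approx(sm_value, rel=1e-6)
        assert pval == pytest.approx(sm_p, rel=1e-4)


class TestMancovaReduce:
    def test_planted_sex_kept_null_nuisance_dropped(self, rng):
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            cov = _covariates(80, r)
            design = build_design(cov)
            sex = design.matrix[:, design.groups["sex"][0]]
            y = r.normal(size=(80, 60))
            y[:, :10] += 1.0 * sex[:, None]
            red = mancova_reduce(y, design)
            ok = red.sex_retained and all(
                p not in red.retained for p in ("age_bin", "iq", "scanner", "dvars")
            )
            hits += ok
        assert hits >= int(0.9 * n_rep)

    def test_null_sex_retention_calibrated(self):
        """With a fully null response, sex survives the multivariate test
        in roughly alpha_keep of replicates."""
        n_rep, kept = 500, 0
        for rep in range(n_rep):
            r = np.random.default_rng(10_000 + rep)
            cov = _covariates(40, r)
            design = build_design(cov)
            y = r.normal(size=(40, 30))
            kept += mancova_reduce(y, design).sex_retained
        se = np.sqrt(0.01 * 0.99 / n_rep)
        assert kept / n_rep <= 0.01 + 3 * se

    def test_overwhelming_single_predictor_retained(self, rng):
        cov = _covariates(60, rng)
        design = build_design(cov)
        sex = design.matrix[:, design.groups["sex"][0]]
        y = rng.normal(size=(60, 20)) + 5.0 * sex[:, None]
        red = mancova_reduce(y, design)
        assert red.sex_retained
        assert "sex" in red.retained


class TestVoxelwise:
    def test_planted_beta_recovered(self):
        betas = []
        for rep in range(50):
            r = np.random.default_rng(rep)
            cov = _covariates(100, r)
            design = build_design(cov)
            sex = design.matrix[:, design.groups["sex"][0]]
            y = r.normal(size=(100, 5))
            y[:, 2] += 0.8 * sex
            eff = voxelwise_univariate(y, design)
            betas.append(eff.loc[eff["voxel"] == 2, "beta"].item())
        assert abs(np.mean(betas) - 0.8) < 0.25

    def test_null_pvalues_uniform(self, rng):
        cov = _covariates(60, rng)
        design = build_design(cov)
        y = rng.normal(size=(60, 1000))
        eff = voxelwise_univariate(y, design)
        ks = sps.kstest(eff["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_male_greater_effect_gives_negative_beta(self, rng):
        cov = _covariates(80, rng)
        design = build_design(cov)
        male = (cov["sex"] == "M").to_numpy(float)
        y = rng.normal(size=(80, 3))
        y[:, 0] += 2.0 * male  # M > F at voxel 0
        eff = voxelwise_univariate(y, design)
        assert eff.loc[eff["voxel"] == 0, "beta"].item() < 0

    def test_sex_not_retained_returns_empty(self, rng):
        from netmosaic.stats import ReducedModel

        cov = _covariates(30, rng)
        design = build_design(cov)
        red = ReducedModel([], {}, [], sex_retained=False, response_dim=1)
        eff = voxelwise_univariate(rng.normal(size=(30, 5)), design, red)
        assert len(eff) == 0


class TestFdr:
    def test_enumerated_four_pvalues_one_discovery(self):
        eff = pd.DataFrame(
            {"network": 0, "voxel": range(4), "beta": 1.0, "t": 1.0,
             "p": [0.001, 0.008, 0.039, 0.041]}
        )
        out = fdr_correct(eff, q_level=0.01)
        assert out["significant"].sum() == 1
        assert out.loc[out["p"] == 0.001, "significant"].item()

    def test_all_extreme_pvalues(self):
        ones = pd.DataFrame({"network": 0, "voxel": range(5), "beta": 1.0, "t": 0.0, "p": 1.0})
        assert fdr_correct(ones).significant.sum() == 0
        zeros = ones.assign(p=0.0)
        assert fdr_correct(zeros).significant.sum() == 5

    def test_q_at_least_p(self, rng):
        eff = pd.DataFrame(
            {"network": 0, "voxel": range(100), "beta": 1.0, "t": 1.0,
             "p": rng.uniform(size=100)}
        )
        out = fdr_correct(eff)
        assert (out["q"] >= out["p"] - 1e-15).all()

    def test_matches_brute_force_step_up_small_vectors(self, rng):
        grid = np.array([0.0005, 0.002, 0.0101, 0.02, 0.049, 0.051, 0.3, 1.0])
        for _ in range(500):
            m = rng.integers(1, 7)
            p = rng.choice(grid, size=m)
            eff = pd.DataFrame({"network": 0, "voxel": range(m), "beta": 1.0, "t": 1.0, "p": p})
            out = fdr_correct(eff, q_level=0.05)
            assert np.array_equal(
                out["significant"].to_numpy(), bh_brute_force(p, 0.05)
            )


class TestClusters:
    def test_single_voxel(self):
        out = connected_clusters(np.array([5]), np.array([0.7]), (3, 3, 3))
        assert len(out) == 1
        assert out[0].mean_beta == pytest.approx(0.7)

    def test_corner_sharing_pair_depends_on_connectivity(self):
        shape = (2, 2, 2)
        vox = np.ravel_multi_index(([0, 1], [0, 1], [0, 1]), shape)
        betas = np.ones(2)
        assert len(connected_clusters(vox, betas, shape, connectivity=26)) == 1
        assert len(connected_clusters(vox, betas, shape, connectivity=6)) == 2

    def test_two_islands_mean_betas(self):
        shape = (5, 5, 5)
        island1 = np.ravel_multi_index(([0, 0], [0, 1], [0, 0]), shape)
        island2 = np.ravel_multi_index(([4], [4], [4]), shape)
        vox = np.concatenate([island1, island2])
        betas = np.array([0.2, 0.4, -0.3])
        out = connected_clusters(vox, betas, shape, connectivity=6)
        means = sorted(c.mean_beta for c in out)
        assert means == pytest.approx([-0.3, 0.3])

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_flood_fill_oracle(self, rng, connectivity):
        shape = (8, 8, 8)
        for _ in range(60):
            vol = rng.random(shape) < 0.25
            vox = np.flatnonzero(vol.ravel())
            out = connected_clusters(vox, np.ones(vox.size), shape, connectivity)
            assert clusters_as_sets(out, shape) == flood_fill_oracle(vol, connectivity)

    def test_empty_set_gives_empty_list(self):
        assert connected_clusters(np.array([], dtype=int), np.array([]), (3, 3, 3)) == []


class TestNetworkFraction:
    def _network(self, n_vox):
        from netmosaic.netmap import NetworkSpatialMap

        t_map = np.zeros(1000)
        t_map[:n_vox] = 100.0
        return NetworkSpatialMap(
            network_id=1, t_map=t_map, voxels=np.arange(n_vox), threshold=50.0
        )

    def test_fraction_arithmetic(self):
        net = self._network(250)
        eff = pd.DataFrame(
            {"network": 1, "voxel": np.arange(5), "beta": [0.5, 0.4, 0.3, -0.2, -0.1],
             "t": 1.0, "p": 0.001, "q": 0.001, "significant": True}
        )
        summary = network_fraction(net, eff, (10, 10, 10))
        assert summary.per_direction["F>M"]["count"] == 3
        assert summary.per_direction["M>F"]["count"] == 2
        assert summary.per_direction["F>M"]["fraction"] + summary.per_direction["M>F"][
            "fraction"
        ] == pytest.approx(5 / 250)

    def test_no_significant_voxels_zero_fraction(self):
        net = self._network(100)
        eff = pd.DataFrame(columns=["network", "voxel", "beta", "t", "p", "q", "significant"])
        summary = network_fraction(net, eff, (10, 10, 10))
        assert summary.per_direction["F>M"]["fraction"] == 0.0
        assert summary.per_direction["M>F"]["fraction"] == 0.0

    def test_average_area_is_mean_of_fractions(self):
        net = self._network(100)
        eff = pd.DataFrame(
            {"network": 1, "voxel": [0, 1], "beta": [0.5, -0.5], "t": 1.0,
             "p": 0.001, "q": 0.001, "significant": True}
        )
        s1 = network_fraction(net, eff, (10, 10, 10))
        s2 = network_fraction(self._network(200), eff, (10, 10, 10))
        avg = model_average_area([s1, s2])
        assert avg["F>M"] == pytest.approx((1 / 100 + 1 / 200) / 2)

    def test_split_directions_conserves_total(self, rng):
        eff = pd.DataFrame(
            {"network": 0, "voxel": range(20), "beta": rng.normal(size=20),
             "t": 1.0, "p": 0.001, "q": 0.001, "significant": True}
        )
        f, m = split_directions(eff)
        assert len(f) + len(m) == 20
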