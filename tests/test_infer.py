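"""Likelihoods, model comparison, bootstrap, conversions and excess tests."""

import math

import numpy as np
import pytest

from orthocoal.coalcore import SiteClassCounts
from orthocoal.haploblocks import Block
from orthocoal.infer import (
    ComparisonEntry,
    FitResult,
    blocks_to_category_counts,
    bootstrap_sfs,
    bsfs_loglik,
    compare_models,
    excess_block_test,
    fit,
    map_density_cM_per_block,
    sfs_loglik,
    to_absolute,
)
from orthocoal.models import DemographicModel, ModelVariant
from orthocoal.synth import SyntheticScenario, simulate_block_table
from orthocoal import io as ocio


def simulated_blocks(model, n_blocks, seed):
    sc = SyntheticScenario(model=model, n_blocks=n_blocks, seed=seed)
    return ocio.frame_to_blocks(simulate_block_table(sc))


def make_block(k, og="og", n_sites=150):
    counts = SiteClassCounts(*k)
    from orthocoal.haploblocks import four_gamete_pass

    return Block(og, counts, n_sites, four_gamete_pass(counts))


class TestSfsLoglik:
    def test_invariant_data_approaches_zero_as_theta_vanishes(self):
        counts = {"invariant": 1000}
        lls = [
            sfs_loglik(DemographicModel("Div", theta=th, T=1.0), counts)
            for th in (1e-3, 1e-4, 1e-5)
        ]
        assert all(l < 0 for l in lls)
        assert lls[0] < lls[1] < lls[2]  # increasing toward 0

    def test_category_order_is_irrelevant(self):
        model = DemographicModel("IM", theta=0.002, T=5.0, M=0.05, direction="B->A")
        counts = {"kA": 10, "kB": 7, "kAB": 1, "kAABB": 40, "invariant": 9000}
        permuted = dict(reversed(list(counts.items())))
        assert sfs_loglik(model, counts) == sfs_loglik(model, permuted)

    def test_im2_rejected(self):
        model = DemographicModel("IM2", theta=0.002, T=5.0, M=0.05,
                                 direction="B->A", size_factor=2.0, size_target="B")
        with pytest.raises(ValueError, match="IM2"):
            sfs_loglik(model, {"invariant": 10})


class TestBsfsLoglik:
    def test_single_invariant_block_matches_closed_form(self):
        lam = 0.075
        model = DemographicModel("Div", theta=2 * lam / 150, T=0.0)
        lnL = bsfs_loglik(model, [make_block((0, 0, 0, 0))])
        closed = 6 / (6 + 4 * lam) * 3 / (3 + 3 * lam) * 1 / (1 + 2 * lam)
        assert lnL == pytest.approx(math.log(closed), abs=1e-10)

    def test_duplicate_blocks_double_the_loglik(self):
        model = DemographicModel("Div", theta=0.002, T=4.0)
        one = bsfs_loglik(model, [make_block((1, 0, 0, 2))])
        two = bsfs_loglik(model, [make_block((1, 0, 0, 2))] * 2)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_block_order_and_four_gamete_violators_are_irrelevant(self):
        model = DemographicModel("Div", theta=0.002, T=4.0)
        blocks = [make_block(k) for k in [(1, 0, 0, 2), (0, 1, 0, 0), (0, 0, 0, 5)]]
        violator = make_block((0, 0, 1, 1))
        assert not violator.four_gamete_pass
        a = bsfs_loglik(model, blocks)
        b = bsfs_loglik(model, list(reversed(blocks)) + [violator])
        assert a == pytest.approx(b, rel=1e-12)


class TestFit:
    def test_im_nests_div_and_migration_estimate_collapses(self):
        """On data simulated without migration, IM fits at least as well as
        Div and its migration estimate collapses to the boundary."""
        truth = DemographicModel("Div", theta=0.0025, T=6.0)
        blocks = simulated_blocks(truth, 300, seed=5)
        fits = fit(
            blocks, "bSFS",
            [ModelVariant("Div"), ModelVariant("IM", direction="B->A")],
            n_starts=2, seed=1, options={"maxfev": 300, "fatol": 1e-6},
        )
        div, im = fits
        assert im.lnL >= div.lnL - 1e-6
        assert im.params["M"] < 0.01

    def test_delta_table_has_exactly_one_zero(self):
        blocks = simulated_blocks(DemographicModel("Div", theta=0.002, T=5.0),
                                  150, seed=2)
        counts = blocks_to_category_counts(blocks)
        fits = fit(
            counts, "SFS",
            [ModelVariant("Div"), ModelVariant("IM", direction="A->B"),
             ModelVariant("Div2", size_target="B")],
            n_starts=2, seed=0, options={"maxfev": 300, "fatol": 1e-6},
        )
        comparison = compare_models(fits)
        deltas = [e.delta for e in comparison.entries]
        assert deltas.count(0.0) == 1
        assert all(d <= 0 for d in deltas)

    def test_sfs_mode_rejects_im2(self):
        v = ModelVariant("IM2", direction="A->B", size_target="A")
        with pytest.raises(ValueError, match="IM2"):
            fit({"invariant": 100}, "SFS", [v])

    def test_empty_variant_list_rejected(self):
        with pytest.raises(ValueError):
            fit({"invariant": 100}, "SFS", [])


class TestCompareModels:
    def fr(self, label_class, lnL, collapsed=False, direction=None):
        return FitResult(
            variant=ModelVariant(label_class, direction=direction),
            params={"theta": 0.001, "T": 1.0},
            lnL=lnL, mode="bSFS", n_starts=1, converged=True,
            collapsed=collapsed,
        )

    def test_simple_deltas(self):
        cmp = compare_models([self.fr("Div", -103.0), self.fr("Div2", -100.0)])
        assert [e.delta for e in cmp.entries] == [0.0, -3.0]
        assert cmp.best.label == "Div2"

    def test_order_invariance(self):
        fits = [self.fr("Div", -103.0), self.fr("Div2", -100.0)]
        assert compare_models(fits).entries == compare_models(fits[::-1]).entries

    def test_collapse_is_reported(self):
        collapsed = FitResult(
            variant=ModelVariant("IM2", direction="A->B", size_target="A"),
            params={"theta": 0.001, "T": 1.0, "M": 1e-6, "size_factor": 1.5},
            lnL=-100.0, mode="bSFS", n_starts=1, converged=True, collapsed=True,
        )
        cmp = compare_models([self.fr("Div", -100.5), collapsed])
        entry = next(e for e in cmp.entries if e.label.startswith("IM2"))
        assert entry.collapsed_to == "Div2"

    def test_mixed_modes_rejected(self):
        a = self.fr("Div", -1.0)
        b = self.fr("Div2", -2.0)
        b.mode = "SFS"
        with pytest.raises(ValueError, match="mixed"):
            compare_models([a, b])


class TestBootstrap:
    OPTS = {"options": {"maxfev": 200, "fatol": 1e-6}}

    def test_replicate_count_and_determinism(self):
        blocks = simulated_blocks(
            DemographicModel("Div", theta=0.003, T=4.0), 80, seed=3
        )
        v = ModelVariant("Div")
        a = bootstrap_sfs(blocks, v, B=5, seed=9, **self.OPTS)
        b = bootstrap_sfs(blocks, v, B=5, seed=9, **self.OPTS)
        assert a.n_replicates == 5
        assert len(a.estimates["theta"]) == 5
        assert np.array_equal(a.estimates["theta"], b.estimates["theta"])

    def test_degenerate_identical_blocks_have_zero_sd(self):
        blocks = [make_block((1, 0, 0, 0), og=f"og{i}") for i in range(30)]
        res = bootstrap_sfs(blocks, ModelVariant("Div"), B=4, seed=0, **self.OPTS)
        assert res.sd["theta"] == 0.0

    def test_ci_contains_point(self):
        blocks = simulated_blocks(
            DemographicModel("Div", theta=0.003, T=4.0), 80, seed=3
        )
        res = bootstrap_sfs(blocks, ModelVariant("Div"), B=5, seed=1, **self.OPTS)
        for name, (lo, hi) in res.ci.items():
            assert lo <= res.point[name] <= hi

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sfs([make_block((1, 0, 0, 0))], ModelVariant("Div"), B=1)

    def test_ci_coverage_floor(self):
        """Bootstrap CIs should cover the truth in the vast majority of
        simulated datasets (they are conservative by construction)."""
        truth = DemographicModel("IM", theta=0.0018, T=12.5, M=0.078,
                                 direction="A->B")
        v = ModelVariant("IM", direction="A->B")
        hits_theta = hits_T = 0
        n_data = 10
        for i in range(n_data):
            blocks = simulated_blocks(truth, 400, seed=100 + i)
            res = bootstrap_sfs(blocks, v, B=20, seed=i, n_starts=2, **self.OPTS)
            lo, hi = res.ci["theta"]
            hits_theta += lo <= truth.theta <= hi
            lo, hi = res.ci["T"]
            hits_T += lo <= truth.T <= hi
        assert hits_theta >= 7
        assert hits_T >= 7


class TestAbsoluteQuantities:
    def test_formulas(self):
        est = to_absolute({"theta": 0.00129, "T": 12.0, "M": 0.0},
                          mu=9.15e-9, g=3.0)
        N = 0.00129 / (4 * 9.15e-9)
        assert est.N_anc == pytest.approx(N)
        assert est.t_years == pytest.approx(12.0 * 2 * N * 3.0)
        assert est.introgressed_fraction == 0.0
        assert est.immigrant_waiting_years == math.inf

    def test_introgressed_fraction(self):
        est = to_absolute({"theta": 0.001, "T": 19.8, "M": 0.015})
        assert est.introgressed_fraction == pytest.approx(1 - math.exp(-0.015 * 19.8))

    def test_scaling_homogeneity(self):
        """Scaling theta and mu together leaves N_anc and t invariant."""
        a = to_absolute({"theta": 0.001, "T": 5.0}, mu=1e-8, g=3.0)
        b = to_absolute({"theta": 0.002, "T": 5.0}, mu=2e-8, g=3.0)
        assert a.N_anc == pytest.approx(b.N_anc)
        assert a.t_years == pytest.approx(b.t_years)

    def test_map_density(self):
        assert map_density_cM_per_block(2600.0, 1479) == pytest.approx(1.758, abs=1e-3)


class TestExcessBlocks:
    MODEL = DemographicModel("Div", theta=2 * 0.075 / 150, T=0.0)

    @staticmethod
    def exact_binomial_sf(observed, n, p):
        """Independent oracle: direct summation of the binomial upper tail."""
        return sum(
            math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(observed, n + 1)
        )

    def test_matches_exact_binomial(self):
        blocks = [make_block((0, 0, 0, 0))] * 3 + [make_block((1, 0, 0, 1))] * 7
        out = excess_block_test(blocks, self.MODEL,
                                pinned={"kA", "kB", "kAB", "kAABB"})
        lam = 0.075
        p_closed = 6 / (6 + 4 * lam) * 3 / (3 + 3 * lam) * 1 / (1 + 2 * lam)
        assert out["observed"] == 3
        assert out["p_model"] == pytest.approx(p_closed, abs=1e-10)
        assert out["P_binomial"] == pytest.approx(
            self.exact_binomial_sf(3, 10, p_closed), rel=1e-9
        )

    def test_zero_observed_gives_certainty(self):
        blocks = [make_block((0, 0, 0, 2))] * 5
        out = excess_block_test(blocks, self.MODEL, pinned={"kAABB"})
        assert out["observed"] == 0
        assert out["P_binomial"] == pytest.approx(1.0)

    def test_no_blocks_rejected(self):
        with pytest.raises(ValueError):
            excess_block_test([], self.MODEL, pinned={"kAABB"})
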