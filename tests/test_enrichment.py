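import numpy as np
import pandas as pd
import pytest

from oracles import bh_stepup, lr_test_2x2
from promoscreen.enrichment import bh_fdr, fit_enrichment, run_motif_screen
from promoscreen.motifs import MotifConsensus, MotifLibrary


def _two_by_two(n11, n10, n01, n00, rng=None):
    """member (present n11 / absent n10) vs background (n01 / n00)."""
    member = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    present = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    return member, present


class TestFitEnrichment:
    def test_agrees_with_2x2_lr_oracle(self):
        member, present = _two_by_two(30, 20, 10, 40)
        effect, p, flag = fit_enrichment(member, present, None, predictor="presence")
        log_or, _, p_oracle = lr_test_2x2(30, 20, 10, 40)
        assert flag == ""
        assert effect == pytest.approx(log_or, abs=1e-6)
        assert p == pytest.approx(p_oracle, rel=0.10)
        assert p < 0.01

    def test_reduces_to_glm_with_constant_covariates(self):
        member, present = _two_by_two(30, 20, 10, 40)
        cov = np.column_stack([np.full(100, 0.5), np.full(100, 2000.0)])
        effect, p, _ = fit_enrichment(member, present, cov, predictor="presence")
        log_or, _, _ = lr_test_2x2(30, 20, 10, 40)
        assert effect == pytest.approx(log_or, abs=1e-6)

    def test_null_counts_give_large_p(self, rng):
        member = (rng.random(400) < 0.3).astype(float)
        counts = rng.poisson(2.0, 400)  # independent of membership
        ps = []
        for _ in range(20):
            perm = rng.permutation(member)
            _, p, _ = fit_enrichment(perm, counts, None)
            ps.append(p)
        # p roughly uniform: mean near 0.5, few small values
        assert 0.25 < np.mean(ps) < 0.75
        assert sum(p < 0.01 for p in ps) <= 2

    def test_gc_confounding_absorbed_by_smooth(self):
        """Membership driven by GC, counts depending on GC only (never on
        membership): the covariate-adjusted fit is calm where the naive
        fit alarms."""
        r = np.random.default_rng(0)
        n = 300
        gc = r.uniform(0.3, 0.7, n)
        member = (r.random(n) < 1 / (1 + np.exp(-8 * (gc - 0.5)))).astype(float)
        counts = r.poisson(np.exp(3 * (gc - 0.5)))  # GC-driven, not member-driven
        cov = np.column_stack([gc, np.full(n, 2000.0)])
        _, p_adj, _ = fit_enrichment(member, counts, cov)
        _, p_naive, _ = fit_enrichment(member, counts, None)
        assert p_naive < 0.01  # the confounded fit is fooled
        assert p_adj > 0.01    # the smooth absorbs the GC effect

    def test_constant_predictor_flagged(self):
        member, _ = _two_by_two(10, 10, 10, 10)
        effect, p, flag = fit_enrichment(member, np.zeros(40), None)
        assert (effect, p, flag) == (0.0, 1.0, "constant_predictor")

    def test_complete_separation_falls_back_flagged(self):
        member = np.r_[np.ones(20), np.zeros(20)]
        counts = np.r_[np.ones(20), np.zeros(20)].astype(int)  # perfectly separates
        effect, p, flag = fit_enrichment(member, counts, None, predictor="presence")
        assert flag == "separation"
        assert np.isfinite(effect) and 0 <= p <= 1

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            fit_enrichment(np.ones(40), np.arange(40), None)


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 7), [0.2] * 7)

    def test_matches_stepup_oracle_exactly(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), bh_stepup(p), rtol=0, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _screen_inputs(rng, n_genes=200, n_member=40, enriched_rate=4.0, null_rate=1.0,
                   n_motifs=6):
    genes = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    member = pd.Series(0, index=genes)
    member.iloc[:n_member] = 1
    counts = pd.DataFrame(
        {f"m{j}": rng.poisson(null_rate, n_genes) for j in range(n_motifs)},
        index=genes,
    )
    counts["planted"] = np.r_[
        rng.poisson(enriched_rate, n_member), rng.poisson(null_rate, n_genes - n_member)
    ]
    covs = pd.DataFrame(
        {"gc": rng.uniform(0.35, 0.65, n_genes), "length": 2000.0}, index=genes
    )
    lib = MotifLibrary(
        [MotifConsensus("planted", "planted", ("CAGGTG",))]
        + [MotifConsensus(f"m{j}", f"m{j}", ("TAATT",)) for j in range(n_motifs)]
    )
    # give the seed row generous counts so the min-sites filter keeps all
    counts.iloc[0] = 10
    return counts, member, covs, lib


class TestRunMotifScreen:
    def test_planted_motif_ranks_first(self, rng):
        counts, member, covs, lib = _screen_inputs(rng)
        res = run_motif_screen(counts, member, covs, lib, "g0", 2000, min_sites=1)
        assert res.loc[0, "motif_id"] == "planted"
        assert res.loc[0, "fdr"] < 0.05

    def test_permuted_membership_rarely_significant(self, rng):
        counts, member, covs, lib = _screen_inputs(rng, enriched_rate=1.0)
        alarms = 0
        for _ in range(20):
            perm = pd.Series(rng.permutation(member.to_numpy()), index=member.index)
            res = run_motif_screen(counts, perm, covs, lib, "g0", 2000, min_sites=1)
            alarms += int((res["fdr"] < 0.05).any())
        assert alarms <= 2  # >= 18/20 replicates clean

    def test_min_sites_above_all_counts_gives_empty(self, rng):
        counts, member, covs, lib = _screen_inputs(rng)
        with pytest.warns(UserWarning):
            res = run_motif_screen(counts, member, covs, lib, "g0", 2000, min_sites=99)
        assert res.empty

    def test_fdr_is_bh_over_reported_family(self, rng):
        counts, member, covs, lib = _screen_inputs(rng)
        res = run_motif_screen(counts, member, covs, lib, "g0", 2000, min_sites=1)
        np.testing.assert_allclose(
            res["fdr"].to_numpy(), bh_stepup(res["p_value"].to_list()), atol=1e-12
        )
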