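"""NRPCC gating, WGD rule, multiplicity, cluster detection, clonality classes
and gain timing against closed-form and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from tumorchrono.clonal_architecture import (
    ClusterSet,
    _pi_estimate,
    assign_clonality,
    classify_wgd,
    compute_nrpcc,
    detect_clusters,
    driver_timing_enrichment,
    estimate_multiplicity,
    fit_ccf_mixture,
    is_eligible,
    loh_fraction,
    mcn2_fraction,
    mean_autosomal_cn,
    time_gain,
    time_sample,
)
from tumorchrono.core_io import CNSegment, Mutation, SampleProfile


def _profile(purity=1.0, ploidy=2.0, depth=80.0):
    return SampleProfile("s", purity=purity, ploidy=ploidy,
                         mean_depth=depth, age_dx=60.0)


class TestNrpcc:
    @pytest.mark.parametrize("d,rho,psi,expected", [
        (80.0, 1.0, 2.0, 40.0),
        (80.0, 0.5, 2.0, 20.0),
        (81.7, 0.6, 3.2, 18.02),   # hand evaluation of the formula
    ])
    def test_formula(self, d, rho, psi, expected):
        got = compute_nrpcc(_profile(purity=rho, ploidy=psi, depth=d))
        assert got == pytest.approx(expected, abs=0.01)

    def test_gate(self):
        assert is_eligible(_profile(purity=0.6, depth=80))
        assert not is_eligible(_profile(purity=0.25, depth=80))
        assert not is_eligible(_profile(purity=0.6, depth=10))


class TestWgd:
    @pytest.mark.parametrize("psi,loh,call", [
        (3.5, 0.2, "WGD"),
        (1.8, 0.1, "nWGD"),
        (2.9, 0.0, "WGD"),          # boundary inclusive
        (2.8999, 0.0, "nWGD"),
    ])
    def test_demarcation(self, psi, loh, call):
        assert classify_wgd(psi, loh) == call

    def test_genome_fractions_are_length_weighted(self):
        segs = [
            CNSegment("chr1", 0, 300, 2, 0),
            CNSegment("chr2", 0, 100, 1, 1),
            CNSegment("chrX", 0, 1000, 5, 0),   # excluded: not autosomal
        ]
        assert loh_fraction(segs) == pytest.approx(0.75)
        assert mcn2_fraction(segs) == pytest.approx(0.75)
        assert mean_autosomal_cn(segs) == pytest.approx((300 * 2 + 100 * 2) / 400)


class TestMultiplicity:
    @pytest.mark.parametrize("f,rho,n_tot,m_raw", [
        (0.5, 1.0, 2, 1.0),
        (0.5, 0.5, 2, 2.0),
        (0.25, 0.8, 3, 0.875),      # hand evaluation
    ])
    def test_raw_multiplicity(self, f, rho, n_tot, m_raw):
        mut = Mutation("chr1", 10, "C", "T",
                       alt_reads=int(f * 1000), total_reads=1000)
        seg = CNSegment("chr1", 0, 100, n_tot - 1, 1)
        got, _ = estimate_multiplicity(mut, seg, rho)
        assert got == pytest.approx(m_raw, rel=1e-6)

    def test_integer_state_prefers_likely_copy_number(self):
        # VAF 0.5 at purity 1 in a (2,2) segment: m=2 at CCF 1
        mut = Mutation("chr1", 10, "C", "T", alt_reads=200, total_reads=400)
        seg = CNSegment("chr1", 0, 100, 2, 2)
        _, m = estimate_multiplicity(mut, seg, 1.0)
        assert m == 2

    def test_zero_copy_segment_excluded(self):
        mut = Mutation("chr1", 10, "C", "T", alt_reads=5, total_reads=10)
        with pytest.raises(ValueError):
            estimate_multiplicity(mut, CNSegment("chr1", 0, 100, 0, 0), 0.5)


class TestClusterDetection:
    def _draw(self, rng, n, depth, locs, weights):
        z = rng.choice(len(locs), p=weights, size=n)
        tot = rng.poisson(depth, size=n).clip(min=1)
        p = 0.5 * np.asarray(locs)[z]
        alt = rng.binomial(tot, p)
        return alt.astype(float), tot.astype(float), np.full(n, 0.5)

    def test_pure_clonal_yields_single_cluster(self):
        rng = np.random.default_rng(0)
        alt, tot, q = self._draw(rng, 2000, 60, [1.0], [1.0])
        cs = detect_clusters(alt, tot, q, seed=0)
        assert cs.k == 1
        assert cs.clonal_ccf == pytest.approx(1.0, abs=0.05)

    def test_two_cluster_mixture_recovered(self):
        rng = np.random.default_rng(1)
        alt, tot, q = self._draw(rng, 3000, 60, [1.0, 0.4], [0.7, 0.3])
        cs = detect_clusters(alt, tot, q, seed=0)
        assert cs.has_subclone()
        sub = min(cs.locations)
        assert sub == pytest.approx(0.4, abs=0.05)

    def test_few_mutations_fall_back_to_single_cluster(self):
        rng = np.random.default_rng(2)
        alt, tot, q = self._draw(rng, 20, 60, [1.0, 0.4], [0.7, 0.3])
        with pytest.warns(UserWarning, match="fallback"):
            cs = detect_clusters(alt, tot, q, seed=0)
        assert cs.k == 1

    def test_em_increases_likelihood_with_k(self):
        rng = np.random.default_rng(3)
        alt, tot, q = self._draw(rng, 1000, 60, [1.0, 0.4], [0.6, 0.4])
        l1 = fit_ccf_mixture(alt, tot, q, 1).loglik
        l2 = fit_ccf_mixture(alt, tot, q, 2).loglik
        assert l2 > l1


class TestClonality:
    def test_gain_classes(self):
        gained = CNSegment("chr1", 0, 100, 2, 1)
        diploid = CNSegment("chr1", 0, 100, 1, 1)
        assert assign_clonality(2, gained, True) == "early_clonal"
        assert assign_clonality(1, gained, True) == "late_clonal"
        assert assign_clonality(1, diploid, True) == "clonal_unspecified"
        assert assign_clonality(1, gained, False) == "subclonal"

    def test_multiplicity_and_clonality_recovery_at_high_nrpcc(self, small_cohort):
        """At NRPCC >= 30, >= 95% of mutations get their true (m, clonality)."""
        from tumorchrono.synthetic_cohort import SimConfig, simulate_cohort

        config = SimConfig(n_samples=2, seed=11, n_snvs=2000, depth=150.0,
                           purity_range=(0.8, 0.8), driver_prob=0.0)
        cohort, truth = simulate_cohort(config)
        pm = truth.per_mutation.set_index(["sample_id", "key"])
        for sid, data in cohort:
            assert compute_nrpcc(data.profile) >= 30
            st = time_sample(data, seed=0)
            hits = 0
            for tm in st.timed:
                t = pm.loc[(sid, tm.mutation.key)]
                true_sub = t.clone > 0
                est_sub = tm.clonality == "subclonal"
                hits += (tm.multiplicity == t.m_true) and (true_sub == est_sub)
            assert hits / len(st.timed) >= 0.95


class TestGainTiming:
    def test_no_duplicated_mutations_means_time_zero(self):
        gt = time_gain(0, (2, 1), n2=0, n1=30)
        assert gt.pi == 0.0

    def test_equal_counts_in_2_1_is_time_one(self):
        gt = time_gain(0, (2, 1), n2=20, n1=20)
        assert gt.pi == pytest.approx(1.0)
        assert gt.ci_low <= gt.pi <= gt.ci_high

    def test_scale_invariance(self):
        for c in (2, 5, 17):
            assert _pi_estimate((2, 2), 30, 50) == \
                pytest.approx(_pi_estimate((2, 2), c * 30, c * 50))

    def test_below_minimum_count_untimed(self):
        assert time_gain(0, (2, 1), n2=1, n1=2) is None
        assert time_gain(0, (3, 2), n2=50, n1=50) is None

    def test_closed_form_equals_grid_likelihood_maximizer(self):
        """The estimator maximizes the profile Poisson likelihood (grid 0.001)."""
        def expected(state, pi):
            if state == (2, 1):
                return pi, 3 - 2 * pi
            if state == (2, 2):
                return 2 * pi, 4 * (1 - pi)
            return pi, 2 * (1 - pi)

        rng = np.random.default_rng(5)
        grid = np.arange(0, 1.0005, 0.001)
        for state in ((2, 1), (2, 2), (2, 0)):
            for _ in range(10):
                pi_true = rng.uniform(0, 1)
                e2, e1 = expected(state, pi_true)
                n2, n1 = rng.poisson(300 * e2), rng.poisson(300 * e1)
                if n2 + n1 < 5:
                    continue
                e2g, e1g = expected(state, grid)
                c = (n2 + n1) / (e2g + e1g)
                ll = (poisson.logpmf(n2, np.maximum(c * e2g, 1e-12))
                      + poisson.logpmf(n1, np.maximum(c * e1g, 1e-12)))
                best = grid[np.argmax(ll)]
                assert _pi_estimate(state, n2, n1) == pytest.approx(best, abs=0.002)


class TestDriverEnrichment:
    @staticmethod
    def _records(a, b, c, d, gene="TP53"):
        rows = ([{"gene": gene, "label": True, "early": True}] * a
                + [{"gene": gene, "label": True, "early": False}] * b
                + [{"gene": gene, "label": False, "early": True}] * c
                + [{"gene": gene, "label": False, "early": False}] * d)
        return pd.DataFrame(rows)

    def test_perfect_separation(self):
        out = driver_timing_enrichment(self._records(10, 0, 0, 10))
        assert out.loc[0, "odds_ratio"] == np.inf
        assert out.loc[0, "p"] < 0.01

    def test_symmetry_gives_unit_odds(self):
        out = driver_timing_enrichment(self._records(5, 5, 5, 5))
        assert out.loc[0, "odds_ratio"] == pytest.approx(1.0)

    def test_cross_product_odds_ratio(self):
        out = driver_timing_enrichment(self._records(30, 20, 15, 25))
        assert out.loc[0, "odds_ratio"] == pytest.approx(2.5)

    def test_zero_margin_gene_skipped(self):
        df = pd.concat([self._records(30, 20, 15, 25),
                        self._records(0, 10, 0, 10, gene="EGFR")])
        out = driver_timing_enrichment(df)
        assert list(out["gene"]) == ["TP53"]
        assert "fdr" in out.columns
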