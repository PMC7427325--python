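"""Clonality fitting, detection sensitivity, and burden adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cryptevolve as ce
from cryptevolve.sensitivity import TruncatedBinomialClonality


class TestDuplicateSensitivity:
    @pytest.mark.parametrize("n1,n2,expected", [
        (0, 50, 1.0),
        (20, 90, 0.9),
        (100, 0, 0.0),
    ])
    def test_formula(self, n1, n2, expected):
        assert ce.duplicate_sensitivity(n1, n2) == pytest.approx(expected)

    def test_no_observations_error(self):
        with pytest.raises(ValueError):
            ce.duplicate_sensitivity(0, 0)

    def test_consistent_with_simulated_duplicates(self):
        n1, n2 = ce.simulate_duplicates("c", 0.8, 100_000, seed=4)
        assert ce.duplicate_sensitivity(n1, n2) == pytest.approx(0.8, abs=0.01)


class TestClonality:
    def test_untruncated_deep_data_recovers_half(self):
        rng = np.random.default_rng(0)
        n = rng.poisson(100, 300)
        k = rng.binomial(n, 0.5)
        est = TruncatedBinomialClonality(truncation=0).fit(k, n)
        assert est.vaf_ == pytest.approx(0.5, abs=0.01)

    def test_truncation_correction_beats_naive_median(self):
        """At v=0.3, depth 15, threshold 3 the naive detected-site median VAF
        is biased up; the truncated fit is not."""
        rng = np.random.default_rng(1)
        n = rng.poisson(15, 2000)
        k = rng.binomial(n, 0.3)
        det = k >= 3
        naive = np.median(k[det] / n[det])
        est = TruncatedBinomialClonality(truncation=3).fit(k, n)
        assert naive > 0.3 + 0.01
        assert est.vaf_ == pytest.approx(0.3, abs=0.02)

    @pytest.mark.parametrize("v", [0.3, 0.4, 0.5])
    def test_recovery_within_two_percent(self, v):
        """|v_hat - v| <= 0.02 at 500 sites, 18x, truncation at 3 reads."""
        rng = np.random.default_rng(int(v * 100))
        n = rng.poisson(18, 500)
        k = rng.binomial(n, v)
        est = TruncatedBinomialClonality(truncation=3).fit(k, n)
        assert abs(est.vaf_ - v) <= 0.02

    def test_grid_search_oracle(self):
        """ML solution matches an independent coarse grid search."""
        rng = np.random.default_rng(3)
        n = rng.poisson(18, 400)
        k = rng.binomial(n, 0.35)
        est = TruncatedBinomialClonality(truncation=3).fit(k, n)
        grid = np.linspace(0.05, 0.5, 451)
        det = (k >= 3) & (n > 0)
        ll = np.array([
            (stats.binom.logpmf(k[det], n[det], v)
             - np.log(stats.binom.sf(2, n[det], v))).sum() for v in grid
        ])
        assert est.vaf_ == pytest.approx(grid[np.argmax(ll)], abs=2e-3)

    def test_no_usable_sites_raises(self):
        with pytest.raises(ValueError):
            TruncatedBinomialClonality().fit([0, 1], [0, 0])

    def test_few_sites_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="falling back"):
            est = TruncatedBinomialClonality(min_sites=10, fallback=0.44).fit(
                [5, 6, 7], [12, 14, 13]
            )
        assert est.vaf_ == 0.44
        assert est.degenerate_


class TestCryptSensitivity:
    def test_closed_form_example(self):
        # lambda=18.2, v=0.5: P(Pois(9.1) >= 4)
        want = stats.poisson.sf(3, 9.1)
        assert ce.crypt_sensitivity(0.5, 18.2) == pytest.approx(want)
        assert 0.97 < want < 0.99

    def test_limits(self):
        assert ce.crypt_sensitivity(1e-6, 18.0) < 1e-10
        assert ce.crypt_sensitivity(0.5, 1e4) == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            lam = rng.uniform(8, 40)
            v = rng.uniform(0.1, 0.6)
            closed = ce.crypt_sensitivity(v, lam)
            mc = ce.crypt_sensitivity(v, lam, method="mc", n_draws=100_000,
                                      seed=int(rng.integers(2**31)))
            se = np.sqrt(closed * (1 - closed) / 100_000)
            assert abs(mc - closed) < 3 * se + 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ce.crypt_sensitivity(0.0, 18.0)
        with pytest.raises(ValueError):
            ce.crypt_sensitivity(0.5, 0.0)


class TestBranchSensitivity:
    @pytest.mark.parametrize("ss,want", [
        ([0.9], 0.9),
        ([0.9, 0.9], 0.99),
        ([1.0, 0.2, 0.3], 1.0),
    ])
    def test_formula(self, ss, want):
        assert ce.branch_sensitivity(ss) == pytest.approx(want)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ce.branch_sensitivity([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
    def test_dominates_best_daughter(self, ss):
        assert ce.branch_sensitivity(ss) >= max(ss) - 1e-12


class TestAdjustCounts:
    def test_terminal_branch_inflation(self):
        tree = ce.CryptPhylogeny.from_newick("(c1:1,c2:1);")
        # terminal branch of c1 carries 90 observed at Ss=0.9
        for b in tree.branch_ids:
            tree.observed_count[b] = 0.0
        t1 = next(b for b in tree.branch_ids
                  if tree.descendants(b) == frozenset({"c1"}))
        tree.observed_count[t1] = 90.0
        ce.adjust_counts(tree, {"c1": 0.9, "c2": 0.9})
        assert tree.adjusted_count[t1] == pytest.approx(100.0)

    def test_cherry_stem_inflated_less(self):
        tree = ce.CryptPhylogeny.from_newick("((c1:0.5,c2:0.5):0.5,c3:1);")
        for b in tree.branch_ids:
            tree.observed_count[b] = 0.0
        stem = next(b for b in tree.branch_ids
                    if tree.descendants(b) == frozenset({"c1", "c2"}))
        tree.observed_count[stem] = 98.0
        ce.adjust_counts(tree, {"c1": 0.9, "c2": 0.9, "c3": 0.9})
        assert tree.adjusted_count[stem] == pytest.approx(98 / 0.99)
        assert 98 / 0.99 < 98 / 0.9  # less inflation than a terminal branch

    def test_unit_sensitivity_is_identity(self):
        tree = ce.CryptPhylogeny.from_newick("((c1:0.5,c2:0.5):0.5,c3:1);")
        for b in tree.branch_ids:
            tree.observed_count[b] = 7.0
        ce.adjust_counts(tree, {c: 1.0 for c in tree.crypts})
        assert all(tree.adjusted_count[b] == 7.0 for b in tree.branch_ids)

    def test_adjusted_never_below_observed(self, small_cohort):
        _, _, meta, truth = small_cohort
        pid = "P001"
        tree = truth.trees[pid]
        ce.adjust_counts(tree, {c: truth.sensitivity[c] for c in tree.crypts})
        for b in tree.branch_ids:
            assert tree.adjusted_count[b] >= tree.observed_count[b]

    def test_missing_crypt_raises(self):
        tree = ce.CryptPhylogeny.from_newick("(c1:1,c2:1);")
        tree.observed_count = {b: 1.0 for b in tree.branch_ids}
        with pytest.raises(ValueError, match="missing Ss"):
            ce.adjust_counts(tree, {"c1": 0.9})


def test_adjusted_burden_recovers_thinned_truth():
    """Detection thinning at ~18-30x coverage: mean relative error of
    adjusted crypt burdens stays within a few percent across seeds."""
    rel_errs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        cfg = ce.CohortConfig(
            n_patients_case=1, n_patients_control=0, biopsies_per_patient=2,
            crypts_per_biopsy=3, age_sub_rate=3.0, disease_sub_rate=3.0,
            patient_sd_case=10, biopsy_sd_case=10, indel_patient_sd_case=1,
            indel_biopsy_sd_case=1, age_indel_rate=0.0, disease_indel_rate=0.0,
            n_germline=0, n_artifact=0,
            mean_coverage=float(rng.uniform(15, 30)), seed=seed,
        )
        _, meta, truth = ce.simulate_cohort(cfg, genotypes=False)
        tree = truth.trees["P001"]
        # thin branch counts by true branch sensitivity (threshold 3 reads)
        ss_true = truth.sensitivity
        observed = {}
        for b in tree.branch_ids:
            sb = ce.branch_sensitivity([ss_true[c] for c in tree.descendants(b)])
            observed[b] = float(rng.binomial(int(tree.observed_count[b]), sb))
        tree.observed_count = observed
        ce.adjust_counts(tree, ss_true)
        adj = tree.crypt_totals(adjusted=True)
        true_tot = truth.burdens.set_index("crypt")["subs_burden"]
        rel = (adj - true_tot.loc[adj.index]) / true_tot.loc[adj.index]
        rel_errs.append(rel.mean())
    assert abs(np.mean(rel_errs)) <= 0.02
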