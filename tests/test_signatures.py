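"""Spectrum channels, EM exposures, reconstitution, cosine matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cryptevolve as ce
from cryptevolve.signatures import SBS96, cosine_similarity, _em_single


class TestChannels:
    def test_96_channels_lexicographic(self):
        assert len(SBS96) == 96
        assert SBS96[0] == "A[C>A]A"
        assert SBS96[-1] == "T[T>G]T"
        assert SBS96 == sorted(SBS96)

    def test_pyrimidine_context(self):
        assert ce.snv_channel("ACG", "C", "T") == "A[C>T]G"

    def test_purine_reverse_complemented(self):
        # G>A on the purine strand reads C>T on the pyrimidine strand
        assert ce.snv_channel("CGT", "G", "A") == "A[C>T]G"

    def test_bad_context_raises(self):
        with pytest.raises(ValueError):
            ce.snv_channel("ANG", "N", "T")
        with pytest.raises(ValueError):
            ce.snv_channel("ACG", "T", "A")


def test_build_spectra_exact_recovery(tmp_path):
    """Planted channel counts on a synthetic contig come back exactly."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    fa = tmp_path / "genome.fa"
    fa.write_text(">chr1\n" + seq + "\n")
    import pyfaidx

    fasta = pyfaidx.Fasta(str(fa))
    tree = ce.CryptPhylogeny.from_newick("(c1:1,c2:1);")
    planted = {}
    sites = []
    muts = []
    for i in range(300):
        pos = int(rng.integers(2, len(seq) - 1))  # 1-based, inside contig
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        ch = ce.snv_channel(seq[pos - 2:pos + 1], ref, alt)
        planted[ch] = planted.get(ch, 0) + 1
        sid = f"s{i}"
        sites.append({"site_id": sid, "chrom": "chr1", "pos": pos,
                      "ref": ref, "alt": alt, "vclass": "SNV"})
        muts.append(sid)
    sites = pd.DataFrame(sites)
    matrix = ce.GenotypeMatrix("P", sites, np.ones((300, 2), int),
                               np.full((300, 2), 9), ["c1", "c2"])
    b0 = tree.branch_ids[-1]
    tree.mutations[b0] = muts
    spectra = ce.build_spectra(tree, matrix, fasta, min_branch_mutations=50)
    assert list(spectra.index) == [b0]
    for ch in SBS96:
        assert spectra.loc[b0, ch] == planted.get(ch, 0)


@pytest.fixture(scope="module")
def sig():
    return ce.make_synthetic_signatures(3, seed=0)


@pytest.fixture(scope="module")
def sig4():
    return ce.make_synthetic_signatures(4, seed=1,
                                        names=["SBS1", "SBS5", "SBS18", "SBS40"])


class TestEM:

    def test_single_signature_dominates(self, sig):
        rng = np.random.default_rng(1)
        x = rng.multinomial(5000, sig.iloc[:, 0])
        e = ce.fit_exposures(pd.Series(x, index=sig.index), sig)
        assert e.iloc[0] / e.sum() >= 0.99

    def test_planted_mixture_recovered(self, sig):
        rng = np.random.default_rng(2)
        mix = 0.7 * sig.iloc[:, 0] + 0.3 * sig.iloc[:, 1]
        x = rng.multinomial(10_000, mix)
        e = ce.fit_exposures(pd.Series(x, index=sig.index), sig)
        frac = e / e.sum()
        assert frac.iloc[0] == pytest.approx(0.7, abs=0.02)
        assert frac.iloc[1] == pytest.approx(0.3, abs=0.02)

    def test_uniform_signature_closed_form(self):
        uni = pd.DataFrame({"U": np.full(96, 1 / 96)}, index=SBS96)
        x = pd.Series(np.arange(96, dtype=float), index=SBS96)
        est = ce.SignatureEM(uni).fit(pd.DataFrame([x]))
        assert est.exposures_.iloc[0, 0] == pytest.approx(x.sum())
        assert est.loglik_[0] == pytest.approx(x.sum() * np.log(1 / 96))

    def test_loglik_monotone_nondecreasing(self, sig):
        rng = np.random.default_rng(3)
        x = rng.multinomial(500, (sig.iloc[:, 0] + sig.iloc[:, 2]) / 2)
        est = ce.SignatureEM(sig, tol=0).fit(pd.DataFrame([x], columns=sig.index))
        path = np.array(est.loglik_path_[0])
        assert np.all(np.diff(path) >= -1e-9)

    def test_matches_simplex_grid_search(self, sig):
        """EM equals brute-force maximization over the 3-signature simplex
        (0.01 resolution) within 1e-3 log-likelihood."""
        rng = np.random.default_rng(4)
        mix = 0.5 * sig.iloc[:, 0] + 0.3 * sig.iloc[:, 1] + 0.2 * sig.iloc[:, 2]
        x = rng.multinomial(2000, mix).astype(float)
        F = sig.to_numpy()
        e, ll, _, _ = _em_single(x, F, 1e-10, 10_000)
        best = -np.inf
        for i in range(101):
            for j in range(101 - i):
                w = np.array([i, j, 100 - i - j]) / 100.0
                m = np.clip(F @ w, 1e-300, None)
                best = max(best, float(x @ np.log(m)))
        assert ll >= best - 1e-3

    def test_zero_spectrum_zero_exposures(self, sig):
        e = ce.fit_exposures(pd.Series(0, index=sig.index), sig)
        assert (e == 0).all()


class TestReconstitute:

    def test_minor_signatures_dropped(self, sig):
        rng = np.random.default_rng(5)
        mix = 0.88 * sig.iloc[:, 0] + 0.09 * sig.iloc[:, 1] + 0.03 * sig.iloc[:, 2]
        x = pd.Series(rng.multinomial(20_000, mix), index=sig.index)
        e = ce.fit_exposures(x, sig)
        r = ce.reconstitute(e, x, sig)
        active = r[r > 0]
        assert list(active.index) == [sig.columns[0]]
        assert r.sum() == pytest.approx(x.sum(), rel=1e-6)

    def test_all_above_threshold_unchanged(self, sig):
        rng = np.random.default_rng(6)
        mix = (sig.iloc[:, 0] + sig.iloc[:, 1] + sig.iloc[:, 2]) / 3
        x = pd.Series(rng.multinomial(30_000, mix), index=sig.index)
        e = ce.fit_exposures(x, sig)
        r = ce.reconstitute(e, x, sig)
        pd.testing.assert_series_equal(r, e)

    def test_exactly_ten_percent_dropped(self, sig):
        # strict '>': an exposure at exactly 10% is removed
        e = pd.Series({"SIG1": 900.0, "SIG2": 100.0, "SIG3": 0.0})
        x = pd.Series(
            np.round(900 * sig["SIG1"] + 100 * sig["SIG2"]), index=sig.index)
        r = ce.reconstitute(e, x, sig)
        assert r["SIG2"] == 0.0

    def test_never_grows_active_set(self, sig):
        rng = np.random.default_rng(7)
        for _ in range(5):
            w = rng.dirichlet([1, 1, 1])
            x = pd.Series(rng.multinomial(3000, sig.to_numpy() @ w),
                          index=sig.index)
            e = ce.fit_exposures(x, sig)
            r = ce.reconstitute(e, x, sig)
            assert (r > 0).sum() <= (e > 1e-9).sum()


class TestMatchComponents:

    def test_reference_row_matches_itself(self, sig4):
        label, cos, ok = ce.match_components(sig4["SBS1"], sig4)
        assert (label, ok) == ("SBS1", True)
        assert cos == pytest.approx(1.0)

    def test_below_cutoff_flagged(self, sig4):
        rng = np.random.default_rng(8)
        # noisy copy tuned below the 0.95 cutoff
        noisy = 0.55 * sig4["SBS1"] + 0.45 * rng.dirichlet(np.ones(96))
        label, cos, ok = ce.match_components(noisy, sig4)
        if cos < 0.95:
            assert not ok
        # construct a guaranteed sub-threshold component: uniform vector
        uni = pd.Series(np.full(96, 1 / 96), index=sig4.index)
        _, cos_u, ok_u = ce.match_components(uni, sig4)
        assert cos_u < 0.95 and not ok_u

    def test_flat_pair_merged_label(self, sig4):
        label, _, _ = ce.match_components(sig4["SBS40"], sig4)
        assert label == "SBS5"

    def test_zero_vector_raises(self, sig4):
        with pytest.raises(ValueError):
            ce.match_components(pd.Series(0.0, index=sig4.index), sig4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_cosine_symmetric_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        a, b = rng.random(96) + 1e-6, rng.random(96) + 1e-6
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        assert cosine_similarity(a * scale, b) == pytest.approx(
            cosine_similarity(a, b))


class TestSignatureBurdens:
    def test_single_signature_equals_total(self):
        tree = ce.CryptPhylogeny.from_newick("((c1:0.5,c2:0.5):0.5,c3:1);")
        tree.observed_count = {b: 10.0 for b in tree.branch_ids}
        expo = pd.DataFrame({"S1": {b: 10.0 for b in tree.branch_ids}})
        out = ce.signature_burdens(expo, tree)
        totals = tree.crypt_totals()
        for c in tree.crypts:
            assert out.loc[c, "S1"] == pytest.approx(totals[c])
            assert out.loc[c, "unassigned"] == 0

    def test_conservation_with_unassigned_small_branches(self):
        tree = ce.CryptPhylogeny.from_newick("((c1:0.5,c2:0.5):0.5,c3:1);")
        tree.observed_count = {b: 20.0 for b in tree.branch_ids}
        fitted = tree.branch_ids[:2]
        expo = pd.DataFrame({"S1": {b: 12.0 for b in fitted},
                             "S2": {b: 8.0 for b in fitted}})
        out = ce.signature_burdens(expo, tree, small_branch="unassigned")
        totals = tree.crypt_totals()
        for c in tree.crypts:
            assert out.loc[c].sum() == pytest.approx(totals[c])

    def test_inherit_uses_ancestor_proportions(self):
        tree = ce.CryptPhylogeny.from_newick("((c1:0.5,c2:0.5):0.5,c3:1);")
        tree.observed_count = {b: 10.0 for b in tree.branch_ids}
        root = tree.branch_ids[-1]
        expo = pd.DataFrame({"S1": {root: 30.0}, "S2": {root: 10.0}})
        out = ce.signature_burdens(expo, tree, small_branch="inherit")
        # every non-root branch inherits 75/25
        assert out.loc["c3", "S1"] == pytest.approx(0.75 * tree.crypt_totals()["c3"])
        assert (out["unassigned"] == 0).all()


def test_signature_tsv_renormalization(tmp_path):
    sig = ce.make_synthetic_signatures(2, seed=2)
    off = sig.copy()
    off.iloc[0, 0] += 5e-5  # sum off by < 1e-4: renormalized with warning
    p = tmp_path / "sigs.tsv"
    off.to_csv(p, sep="\t")
    with pytest.warns(UserWarning, match="renormalizing"):
        back = ce.read_signatures(p)
    assert np.allclose(back.sum(axis=0), 1.0)
    bad = sig.copy()
    bad.iloc[0, 0] += 0.01
    bad.to_csv(p, sep="\t")
    with pytest.raises(ValueError):
        ce.read_signatures(p)
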