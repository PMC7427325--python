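"""Mutational spectra and signature exposure fitting.

A mutational signature is a probability distribution over mutation classes
(96 trinucleotide-context classes for single-base substitutions, keyed to the
pyrimidine strand).  Branches of a crypt phylogeny with enough mutations are
treated as samples: their spectra are deconvoluted into a fixed reference
signature set by expectation maximization on the multinomial likelihood, then
re-fitted using only signatures that account for > 10% of the mutations (to
avoid overfitting), and externally supplied components are matched to
references by cosine similarity with a 0.95 cutoff.  SBS5 and SBS40 are both
flat and hard to distinguish; matches to either are reported under SBS5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

PYRIMIDINES = {"C", "T"}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SBS96 = sorted(
    f"{f5}[{ref}>{alt}]{f3}"
    for ref in "CT"
    for alt in "ACGT"
    if alt != ref
    for f5 in "ACGT"
    for f3 in "ACGT"
)
MERGE_FLAT = {"SBS40": "SBS5"}


def snv_channel(ref_context: str, ref: str, alt: str) -> str:
    """Map an SNV with its 3-base reference context to one of the 96 channels.

    Purine reference bases are reverse-complemented onto the pyrimidine
    strand.  Raises on non-ACGT context.
    """
    ref_context = ref_context.upper()
    if len(ref_context) != 3 or any(b not in COMPLEMENT for b in ref_context):
        raise ValueError(f"bad context {ref_context!r}")
    if ref_context[1] != ref.upper():
        raise ValueError("context middle base does not match ref")
    ref, alt = ref.upper(), alt.upper()
    if ref not in PYRIMIDINES:
        ref_context = "".join(COMPLEMENT[b] for b in reversed(ref_context))
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref_context[0]}[{ref}>{alt}]{ref_context[2]}"


def build_spectra(tree, matrix, fasta, min_branch_mutations: int = 50) -> pd.DataFrame:
    """96-channel spectra for branches with > min_branch_mutations SNVs.

    ``fasta`` is a pyfaidx.Fasta (or any mapping chrom -> indexable sequence).
    SNVs at contig edges or with non-ACGT context are skipped with a warning.
    Returns a DataFrame (branches x SBS96).
    """
    info = matrix.sites.set_index("site_id")
    rows = {}
    n_skipped = 0
    for b in tree.branch_ids:
        muts = [m for m in tree.mutations.get(b, [])
                if info.loc[m, "vclass"] == "SNV"]
        if len(muts) <= min_branch_mutations:
            continue
        counts = pd.Series(0, index=SBS96, dtype=int)
        for m in muts:
            chrom, pos = info.loc[m, "chrom"], int(info.loc[m, "pos"])
            try:
                ctx = str(fasta[chrom][pos - 2:pos + 1])
                ch = snv_channel(ctx, info.loc[m, "ref"], info.loc[m, "alt"])
            except (ValueError, KeyError, IndexError):
                n_skipped += 1
                continue
            counts[ch] += 1
        rows[b] = counts
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} SNVs with unresolvable context")
    return pd.DataFrame(rows).T.reindex(columns=SBS96, fill_value=0)


def read_signatures(path, renorm_tol: float = 1e-4) -> pd.DataFrame:
    """Read a reference signature TSV (channels as rows, signatures as columns).

    Each signature must sum to 1 within 1e-6; sums off by up to ``renorm_tol``
    are renormalized with a warning, larger deviations raise.
    """
    sig = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signatures(sig, renorm_tol=renorm_tol)


def validate_signatures(sig: pd.DataFrame, renorm_tol: float = 1e-4) -> pd.DataFrame:
    if (sig.to_numpy() < 0).any():
        raise ValueError("negative signature probabilities")
    sums = sig.sum(axis=0)
    off = (sums - 1).abs()
    if (off > renorm_tol).any():
        bad = list(sums.index[off > renorm_tol])
        raise ValueError(f"signatures do not sum to 1: {bad}")
    if (off > 1e-6).any():
        warnings.warn("renormalizing signatures with sums off by <= 1e-4")
        sig = sig / sums
    return sig


def write_signatures(sig: pd.DataFrame, path) -> None:
    sig.to_csv(path, sep="\t")


class SignatureEM(BaseEstimator):
    """Nonnegative signature exposures by multinomial EM.

    Given channel counts x and reference signatures F (channels x S), EM
    maximizes sum_c x_c log(sum_s w_s F_cs) over exposure fractions w on the
    simplex, with the classic multiplicative update; the log-likelihood is
    non-decreasing every iteration.  Exposures are reported on the mutation
    count scale (w_s * sum(x)).

    Parameters
    ----------
    signatures : DataFrame (channels x signatures), columns summing to 1.
    tol : float
        Convergence threshold on the relative log-likelihood change.
    max_iter : int

    Attributes
    ----------
    exposures_ : DataFrame (samples x signatures), count scale.
    loglik_ : per-sample final log-likelihood (multinomial, up to a constant).
    n_iter_ : per-sample iteration counts.
    """

    def __init__(self, signatures: pd.DataFrame, tol: float = 1e-8,
                 max_iter: int = 10_000):
        self.signatures = signatures
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X):
        sig = validate_signatures(self.signatures)
        X = pd.DataFrame(X)
        X = X.reindex(columns=sig.index, fill_value=0)
        F = sig.to_numpy(dtype=float)  # (C, S)
        expo, lls, iters, paths = [], [], [], []
        for _, row in X.iterrows():
            e, ll, it, path = _em_single(row.to_numpy(dtype=float), F,
                                         self.tol, self.max_iter)
            expo.append(e)
            lls.append(ll)
            iters.append(it)
            paths.append(path)
        self.exposures_ = pd.DataFrame(expo, index=X.index, columns=sig.columns)
        self.loglik_ = np.asarray(lls)
        self.n_iter_ = np.asarray(iters)
        self.loglik_path_ = paths
        return self

    def transform(self, X):
        return self.fit(X).exposures_

    fit_transform = transform


def _em_single(x, F, tol, max_iter):
    n = x.sum()
    S = F.shape[1]
    if n == 0:
        return np.zeros(S), 0.0, 0, [0.0]
    w = np.full(S, 1.0 / S)
    path = []
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        m = F @ w  # (C,)
        m = np.clip(m, 1e-300, None)
        ll = float(x @ np.log(m))
        path.append(ll)
        if ll - ll_old <= tol * max(1.0, abs(ll)):
            break
        ll_old = ll
        w = w * (F.T @ (x / m))
        w /= w.sum()
    return w * n, ll, it, path


def fit_exposures(spectrum, signatures: pd.DataFrame, tol: float = 1e-8,
                  max_iter: int = 10_000) -> pd.Series:
    """EM exposures (count scale) for one spectrum; see SignatureEM."""
    est = SignatureEM(signatures, tol=tol, max_iter=max_iter)
    est.fit(pd.DataFrame([pd.Series(spectrum)]))
    return est.exposures_.iloc[0]


def reconstitute(exposures: pd.Series, spectrum, signatures: pd.DataFrame,
                 min_fraction: float = 0.10, tol: float = 1e-8,
                 max_iter: int = 10_000) -> pd.Series:
    """Refit keeping only signatures that explain > min_fraction of mutations.

    Signatures at or below the threshold (strict >) are dropped, smallest
    first, and the survivors are refitted; this iterates until stable.  If
    every signature would be dropped the single largest is retained with a
    warning.  The active set never grows.
    """
    active = list(exposures.index)
    expo = exposures.copy()
    while True:
        total = expo.sum()
        if total == 0:
            break
        frac = expo / total
        low = frac[frac <= min_fraction]
        if low.empty:
            break
        if len(low) == len(active):
            keep = frac.idxmax()
            warnings.warn(f"all signatures <= {min_fraction:.0%}; retaining {keep}")
            active = [keep]
        else:
            active = [s for s in active if s not in set(low.index)]
        refit = fit_exposures(spectrum, signatures[active], tol=tol,
                              max_iter=max_iter)
        expo = refit.reindex(exposures.index, fill_value=0.0)
        if set(expo[expo / max(expo.sum(), 1e-300) > min_fraction].index) == set(active) \
                or len(active) == 1:
            break
    return expo


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no cosine similarity")
    return float(a @ b / (na * nb))


def match_components(component, signatures: pd.DataFrame,
                     threshold: float = 0.95,
                     merge: dict | None = None) -> tuple[str, float, bool]:
    """Best cosine match of a spectrum component against reference signatures.

    Returns (label, cosine, matched); matched is False below ``threshold``,
    flagging the component for EM decomposition.  Labels in ``merge``
    (default SBS40 -> SBS5) are reported under their merged name.
    """
    component = pd.Series(component)
    sims = {s: cosine_similarity(component.reindex(signatures.index, fill_value=0),
                                 signatures[s]) for s in signatures.columns}
    best = max(sims, key=sims.get)
    cos = sims[best]
    merge = MERGE_FLAT if merge is None else merge
    return merge.get(best, best), cos, cos >= threshold


def signature_burdens(exposures: pd.DataFrame, tree,
                      small_branch: str = "inherit") -> pd.DataFrame:
    """Per-crypt per-signature burdens as path sums of branch exposures.

    Branches absent from ``exposures`` (below the spectrum size threshold)
    either inherit the nearest fitted ancestor's exposure proportions applied
    to their own mutation count (``"inherit"``) or contribute their count as
    unassigned (``"unassigned"``).
    """
    if small_branch not in ("inherit", "unassigned"):
        raise ValueError("small_branch must be 'inherit' or 'unassigned'")
    sig_cols = list(exposures.columns)
    out = pd.DataFrame(0.0, index=tree.crypts, columns=sig_cols + ["unassigned"])
    fitted = set(exposures.index)
    for crypt in tree.crypts:
        path = tree.crypt_path(crypt)
        for b in path:
            count = tree.observed_count.get(b, float(len(tree.mutations.get(b, []))))
            if count == 0:
                continue
            if b in fitted:
                row = exposures.loc[b]
                tot = row.sum()
                if tot > 0:
                    out.loc[crypt, sig_cols] += row.to_numpy() * (count / tot)
                else:
                    out.loc[crypt, "unassigned"] += count
            else:
                anc = _nearest_fitted_ancestor(tree, b, fitted, path)
                if small_branch == "inherit" and anc is not None:
                    row = exposures.loc[anc]
                    out.loc[crypt, sig_cols] += row.to_numpy() / row.sum() * count
                else:
                    out.loc[crypt, "unassigned"] += count
    return out


def _nearest_fitted_ancestor(tree, branch, fitted, path):
    i = path.index(branch)
    for b in reversed(path[:i]):
        if b in fitted:
            return b
    return None


def make_synthetic_signatures(n_signatures: int = 3, seed: int = 0,
                              channels=None, sharpness: float = 0.9,
                              names=None) -> pd.DataFrame:
    """Well-separated synthetic reference signatures for simulation and tests.

    Channels are partitioned into blocks; each signature puts ``sharpness``
    of its mass (Dirichlet-distributed) on its own block and spreads the rest
    uniformly, giving low pairwise cosine similarity.
    """
    channels = SBS96 if channels is None else list(channels)
    rng = np.random.default_rng(seed)
    C = len(channels)
    blocks = np.array_split(np.arange(C), n_signatures)
    cols = {}
    if names is None:
        names = [f"SIG{i + 1}" for i in range(n_signatures)]
    for name, block in zip(names, blocks):
        v = np.full(C, (1 - sharpness) / (C - len(block)))
        v[block] = sharpness * rng.dirichlet(np.full(len(block), 2.0))
        cols[name] = v / v.sum()
    return pd.DataFrame(cols, index=channels)
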