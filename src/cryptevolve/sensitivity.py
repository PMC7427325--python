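"""Detection sensitivity of somatic mutation calls and burden adjustment.

Low-coverage whole genomes miss real mutations, and the miss rate depends on
the crypt's clonality (its true median VAF, < 0.5 because of stromal
contamination and recent, unfixed mutations).  Per crypt we estimate:

* clonality ``v`` by fitting a truncated binomial to the variant-read counts
  of its somatic mutations — truncated because counts below the calling
  threshold are never observed, which biases the naive median VAF upward;
* sensitivity ``Ss`` as the probability that a mutation present at VAF ``v``
  yields enough mutant reads at Poisson(lambda) coverage, either by
  simulating call attempts or by the closed form
  P(Poisson(lambda * v) >= min_mut_reads);
* branch sensitivity ``Sb = 1 - prod_i(1 - Ss_i)`` over the branch's daughter
  crypts — a branch mutation is seen if any descendant crypt detects it;
* adjusted branch counts ``observed / Sb``, so stand-alone crypts are
  augmented more than clades with many daughters.

An independent, design-based estimate of per-call sensitivity comes from
crypts dissected and sequenced twice: with ``n2`` mutations called in both
replicates and ``n1`` in exactly one, the ML estimate (mutations missed by
both going unobserved) is ``S = 2 n2 / (n1 + 2 n2)``, a lower bound since the
two replicates share coverage unevenly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .phylo import CryptPhylogeny


def duplicate_sensitivity(n1: int, n2: int) -> float:
    """ML per-call sensitivity from duplicate dissections: 2*n2/(n1+2*n2)."""
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be nonnegative")
    if n1 + n2 == 0:
        raise ValueError("no mutations observed in either replicate")
    return 2.0 * n2 / (n1 + 2.0 * n2)


class TruncatedBinomialClonality(BaseEstimator):
    """ML clonality (median VAF) from truncation-aware binomial fitting.

    The likelihood of variant reads k_i at depth n_i, conditioned on the site
    having been detected (k_i >= t), is Binom(k_i | n_i, v) / P(K >= t | n_i, v).
    ``v`` is maximized on (0, vmax]; vmax defaults to 0.5, the autosomal
    heterozygous ceiling.

    Parameters
    ----------
    truncation : int
        Detection threshold t in variant reads (the pipeline's own support
        filter, 3 by default; set 4 to mirror callers that need 4).
    min_sites : int
        Minimum usable sites; below this the estimate falls back to
        ``fallback`` with a warning.
    vmax : float
        Upper bound for v.
    fallback : float
        Cohort default used when too few sites are available.

    Attributes
    ----------
    vaf_ : the fitted clonality; n_sites_ : sites used; degenerate_ : bool.
    """

    def __init__(self, truncation: int = 3, min_sites: int = 10,
                 vmax: float = 0.5, fallback: float = 0.44):
        self.truncation = truncation
        self.min_sites = min_sites
        self.vmax = vmax
        self.fallback = fallback

    def fit(self, k, n):
        k = np.asarray(k, dtype=float)
        n = np.asarray(n, dtype=float)
        use = (n > 0) & (k >= self.truncation)
        k, n = k[use], n[use]
        if len(k) == 0:
            raise ValueError("no usable sites (all zero-depth or sub-threshold)")
        if len(k) < self.min_sites:
            warnings.warn(
                f"only {len(k)} usable sites; falling back to v={self.fallback}"
            )
            self.vaf_ = float(self.fallback)
            self.n_sites_ = int(len(k))
            self.degenerate_ = True
            return self
        t = self.truncation

        def nll(v):
            with np.errstate(divide="ignore"):
                ll = stats.binom.logpmf(k, n, v)
                denom = stats.binom.sf(t - 1, n, v)
            return -(ll - np.log(np.clip(denom, 1e-300, None))).sum()

        r = minimize_scalar(nll, bounds=(1e-3, self.vmax), method="bounded",
                            options={"xatol": 1e-5})
        self.vaf_ = float(r.x)
        self.n_sites_ = int(len(k))
        self.degenerate_ = False
        return self


def fit_clonality(k, n, truncation: int = 3, min_sites: int = 10,
                  fallback: float = 0.44) -> float:
    """Truncated-binomial clonality estimate (see TruncatedBinomialClonality)."""
    est = TruncatedBinomialClonality(truncation=truncation, min_sites=min_sites,
                                     fallback=fallback).fit(k, n)
    return est.vaf_


def crypt_sensitivity(median_vaf: float, median_coverage: float,
                      n_draws: int = 100_000, min_mut_reads: int = 4,
                      seed: int | None = None, method: str = "closed") -> float:
    """Per-crypt detection sensitivity Ss.

    Mutant reads of a call attempt are Binomial(Poisson(lambda), v), i.e.
    Poisson(lambda*v) by thinning; Ss = P(mutant reads >= min_mut_reads).
    ``method="mc"`` reproduces the simulation procedure (n_draws attempts
    with coverage drawn from Poisson(lambda)); ``"closed"`` evaluates the
    Poisson tail exactly.
    """
    if not 0 < median_vaf < 1:
        raise ValueError("median_vaf must be in (0, 1)")
    if median_coverage <= 0:
        raise ValueError("median_coverage must be positive")
    if method == "closed":
        return float(stats.poisson.sf(min_mut_reads - 1, median_coverage * median_vaf))
    rng = np.random.default_rng(seed)
    cov = rng.poisson(median_coverage, size=n_draws)
    mut = rng.binomial(cov, median_vaf)
    return float(np.mean(mut >= min_mut_reads))


def branch_sensitivity(ss: "list[float]") -> float:
    """Sb = 1 - prod(1 - Ss_i) over a branch's daughter crypts."""
    ss = np.asarray(ss, dtype=float)
    if ss.size == 0:
        raise ValueError("branch has no daughter crypts")
    if np.any((ss <= 0) | (ss > 1)):
        raise ValueError("per-crypt sensitivities must be in (0, 1]")
    return float(1.0 - np.prod(1.0 - ss))


def adjust_counts(tree: CryptPhylogeny, ss: "dict[str, float]") -> CryptPhylogeny:
    """Set per-branch sensitivity and adjusted counts on a tree in place.

    Every branch gets Sb from its daughter crypts' Ss and
    adjusted = observed / Sb.  Requires Ss for every leaf and observed
    counts already set.
    """
    missing = [c for c in tree.crypts if c not in ss]
    if missing:
        raise ValueError(f"missing Ss for crypts: {missing}")
    for b in tree.branch_ids:
        daughters = tree.descendants(b)
        sb = branch_sensitivity([ss[c] for c in daughters])
        if sb == 0:
            raise ValueError(f"branch {b} has zero sensitivity")
        tree.sensitivity[b] = sb
        obs = tree.observed_count.get(b, float(len(tree.mutations.get(b, []))))
        tree.adjusted_count[b] = obs / sb
    return tree
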