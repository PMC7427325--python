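"""Germline / somatic / artifact classification of candidate variant sites.

Candidate sites come as per-crypt variant and total read counts for one
patient.  Three filters are applied, in order:

1. *Aggregated exact binomial test.*  A heterozygous germline variant is
   present in every crypt at VAF 0.5 (0.95 on the sex chromosomes of males,
   reflecting hemizygosity with residual noise).  Reads are pooled over all
   crypts of the patient and a one-sided exact binomial test asks whether the
   pooled VAF is *lower* than the germline expectation.  p-values are BH
   corrected within the patient; a site is a somatic candidate at q < 1e-3
   (q < 1e-2 when fewer than five crypts were dissected).
2. *Beta-binomial overdispersion.*  True somatic variants show presence /
   absence structure across crypts (high intra-class correlation rho);
   artifacts scatter binomially (low rho).  rho is maximized over a log grid
   from 1e-6 to 10**-0.05 with the mean profile-maximized per grid point;
   sites with rho < 0.1 are artifacts.
3. *Read support.*  A somatic site must have at least one crypt with >= 3
   variant reads and depth >= 5; crypt-level presence flags require the same.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

RHO_GRID_DEFAULT = np.logspace(-6, -0.05, 100)


@dataclass
class GenotypeMatrix:
    """Per-patient sites x crypts read counts.

    ``sites`` has columns site_id, chrom, pos (1-based), ref, alt, vclass
    ("SNV" or "indel"); ``var`` and ``dp`` are (n_sites, n_crypts) integer
    arrays of variant-supporting and total reads.
    """

    patient_id: str
    sites: pd.DataFrame
    var: np.ndarray
    dp: np.ndarray
    crypts: list[str]
    sex: str = "female"

    def __post_init__(self):
        self.var = np.asarray(self.var, dtype=np.int64)
        self.dp = np.asarray(self.dp, dtype=np.int64)
        if self.var.shape != self.dp.shape:
            raise ValueError("var/dp shape mismatch")
        if self.var.shape != (len(self.sites), len(self.crypts)):
            raise ValueError("counts shape does not match sites x crypts")
        if np.any(self.var < 0) or np.any(self.var > self.dp):
            raise ValueError("require 0 <= variant_reads <= total_reads")
        if self.sites["site_id"].duplicated().any():
            raise ValueError("duplicate site ids")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def drop_crypt(self, crypt: str) -> "GenotypeMatrix":
        keep = [i for i, c in enumerate(self.crypts) if c != crypt]
        return GenotypeMatrix(self.patient_id, self.sites.copy(),
                              self.var[:, keep], self.dp[:, keep],
                              [self.crypts[i] for i in keep], self.sex)


def aggregate_binomial_test(matrix: GenotypeMatrix) -> pd.Series:
    """One-sided exact binomial p-values against the germline null.

    Reads are aggregated over crypts; p = P(X <= k | X ~ Bin(n, p0)) with
    p0 = 0.5 on autosomes (and on X in females) and 0.95 on X/Y in males.
    Sites with zero aggregate depth get p = NaN (flagged low_support later).
    """
    k = matrix.var.sum(axis=1).astype(float)
    n = matrix.dp.sum(axis=1).astype(float)
    chrom = matrix.sites["chrom"].astype(str).str.replace("chr", "", regex=False)
    p0 = np.where(
        (matrix.sex == "male") & chrom.isin(["X", "Y"]).to_numpy(), 0.95, 0.5
    )
    with np.errstate(divide="ignore"):
        p = stats.binom.cdf(k, n, p0)
    p = np.where(n > 0, p, np.nan)
    return pd.Series(p, index=matrix.sites["site_id"].to_numpy(), name="p_germline")


def classify_germline(pvalues: pd.Series, n_crypts: int) -> pd.DataFrame:
    """BH-correct within the patient and call somatic candidates.

    Threshold is q < 1e-3, relaxed to q < 1e-2 when fewer than five crypts
    were dissected for the patient.
    """
    out = pd.DataFrame(index=pvalues.index)
    out["p_germline"] = pvalues
    out["q_germline"] = np.nan
    ok = pvalues.notna()
    if ok.any():
        out.loc[ok, "q_germline"] = multipletests(
            pvalues[ok].to_numpy(), method="fdr_bh"
        )[1]
    thresh = 1e-3 if n_crypts >= 5 else 1e-2
    out["somatic_candidate"] = out["q_germline"] < thresh
    return out


def betabinomial_loglik(k, n, mu: float, rho: float) -> float:
    """Beta-binomial log-likelihood, mean/intra-class-correlation form.

    Shapes a = mu(1-rho)/rho and b = (1-mu)(1-rho)/rho, so rho -> 0 recovers
    a plain binomial and rho -> 1 a presence/absence mixture.
    """
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return float(stats.betabinom.logpmf(k, n, a, b).sum())


def _betabinom_ll_grid(k, n, mu, rho):
    """Beta-binomial log-likelihood summed over crypts, broadcast over a
    (mu, rho) grid; gammaln form of the same pmf as betabinomial_loglik."""
    from scipy.special import gammaln

    mu = np.asarray(mu, dtype=float)[..., None]   # (..., 1) over crypts
    rho = np.asarray(rho, dtype=float)[..., None]
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    ll = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
          + gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
          + gammaln(a + b) - gammaln(a) - gammaln(b))
    return ll.sum(axis=-1)


def betabinomial_rho(k, n, rho_grid=None) -> tuple[float, float]:
    """Joint ML of (rho, mu) on a log-spaced rho grid, mu profiled per point.

    The mean is profiled by golden-section search on (0, 1), vectorized
    across the whole rho grid.  Returns (rho_hat, mu_hat).  Raises on
    all-zero depths.  A single informative crypt leaves rho unidentified:
    mu_hat is the observed VAF and rho_hat sits at the lower grid boundary
    (degenerate, caller may flag).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    use = n > 0
    if not use.any():
        raise ValueError("site has zero depth in every crypt")
    k, n = k[use], n[use]
    if rho_grid is None:
        rho_grid = RHO_GRID_DEFAULT
    rho_grid = np.asarray(rho_grid, dtype=float)
    if len(k) == 1:
        return float(rho_grid[0]), float(k[0] / n[0])
    ll, mu = _profile_mu_grid(k, n, rho_grid)
    best = int(np.argmax(ll))
    return float(rho_grid[best]), float(mu[best])


def _profile_mu_grid(k, n, rho_grid, lo: float = 1e-6, tol: float = 1e-6,
                     n_iter: int = 40):
    """Golden-section profile of mu for every rho grid point at once."""
    g = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full_like(rho_grid, lo)
    b = np.full_like(rho_grid, 1.0 - lo)
    for _ in range(n_iter):
        c = b - g * (b - a)
        d = a + g * (b - a)
        fc = _betabinom_ll_grid(k, n, c, rho_grid)
        fd = _betabinom_ll_grid(k, n, d, rho_grid)
        left = fc > fd  # maximum lies in [a, d]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        if np.all(b - a < tol):
            break
    mu = (a + b) / 2.0
    return _betabinom_ll_grid(k, n, mu, rho_grid), mu


class BetaBinomialFilter(BaseEstimator):
    """Site classifier: germline / somatic / artifact / low_support.

    Parameters
    ----------
    q_threshold, q_threshold_few : float
        Somatic-candidate q-value cutoffs for >= 5 and < 5 crypts.
    rho_threshold : float
        Beta-binomial overdispersion below which somatic candidates are
        called artifacts, default 0.1.
    min_var_reads, min_depth : int
        Per-crypt read support required for presence (3 reads, depth 5).
    by_class : bool
        BH-correct SNVs and indels as separate families (default True).
    normal_crypt : str or None
        Optional matched non-epithelial sample: sites with germline-like
        support in it are removed before testing, and the column is dropped.
    rho_grid : array or None
        Overrides the default 100-point log grid on [1e-6, 10**-0.05].

    Attributes
    ----------
    verdicts_ : DataFrame indexed by site_id with classification, q_germline,
        rho_hat, mu_hat and per-crypt presence flags.
    presence_ : boolean (n_sites, n_crypts) DataFrame of presence flags.
    """

    def __init__(self, q_threshold: float = 1e-3, q_threshold_few: float = 1e-2,
                 rho_threshold: float = 0.1, min_var_reads: int = 3,
                 min_depth: int = 5, by_class: bool = True,
                 normal_crypt: str | None = None, rho_grid=None):
        self.q_threshold = q_threshold
        self.q_threshold_few = q_threshold_few
        self.rho_threshold = rho_threshold
        self.min_var_reads = min_var_reads
        self.min_depth = min_depth
        self.by_class = by_class
        self.normal_crypt = normal_crypt
        self.rho_grid = rho_grid

    def fit(self, matrix: GenotypeMatrix):
        if self.normal_crypt is not None:
            matrix = self._subtract_normal(matrix)
        n_crypts = len(matrix.crypts)
        sites = matrix.sites.set_index("site_id")

        if self.by_class:
            parts = []
            for _, idx in sites.groupby("vclass").groups.items():
                sub = self._subset(matrix, sites.index.get_indexer(idx))
                p = aggregate_binomial_test(sub)
                parts.append(classify_germline(p, n_crypts))
            cand = pd.concat(parts).reindex(sites.index)
        else:
            cand = classify_germline(aggregate_binomial_test(matrix), n_crypts)

        presence = (matrix.var >= self.min_var_reads) & (matrix.dp >= self.min_depth)
        rho_hat = np.full(len(sites), np.nan)
        mu_hat = np.full(len(sites), np.nan)
        cls = np.empty(len(sites), dtype=object)
        for i, sid in enumerate(sites.index):
            if not np.isfinite(cand["q_germline"].iloc[i]):
                cls[i] = "low_support"
                continue
            if not cand["somatic_candidate"].iloc[i]:
                cls[i] = "germline"
                continue
            if not presence[i].any():
                # no crypt clears the read thresholds: call before the
                # dispersion test, which is unidentifiable at 1-2 reads
                cls[i] = "low_support"
                continue
            try:
                rho_hat[i], mu_hat[i] = betabinomial_rho(
                    matrix.var[i], matrix.dp[i], rho_grid=self.rho_grid
                )
            except ValueError:
                cls[i] = "low_support"
                continue
            cls[i] = "artifact" if rho_hat[i] < self.rho_threshold else "somatic"

        verdicts = cand.copy()
        verdicts["rho_hat"] = rho_hat
        verdicts["mu_hat"] = mu_hat
        verdicts["classification"] = cls
        self.verdicts_ = verdicts
        self.presence_ = pd.DataFrame(presence, index=sites.index,
                                      columns=matrix.crypts)
        self.n_crypts_ = n_crypts
        return self

    def _subset(self, matrix, rows):
        return GenotypeMatrix(matrix.patient_id,
                              matrix.sites.iloc[rows].reset_index(drop=True),
                              matrix.var[rows], matrix.dp[rows],
                              matrix.crypts, matrix.sex)

    def _subtract_normal(self, matrix):
        if self.normal_crypt not in matrix.crypts:
            raise ValueError(f"normal sample {self.normal_crypt!r} not in matrix")
        j = matrix.crypts.index(self.normal_crypt)
        germy = (matrix.var[:, j] >= self.min_var_reads) & (
            matrix.var[:, j] / np.maximum(matrix.dp[:, j], 1) >= 0.2
        )
        if germy.any():
            warnings.warn(f"matched normal removes {int(germy.sum())} sites")
        keep = np.where(~germy)[0]
        out = self._subset(matrix, keep)
        return out.drop_crypt(self.normal_crypt)


def apply_filters(matrix: GenotypeMatrix, **params) -> pd.DataFrame:
    """Run the full filter stack; returns the verdict table."""
    est = BetaBinomialFilter(**params).fit(matrix)
    return est.verdicts_
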