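"""Crypt phylogenies and maximum-likelihood placement of somatic mutations.

A patient's crypts are related by a rooted tree whose leaves are the dissected
crypts.  Each somatic mutation arose once, on one branch, and is therefore
shared by exactly the crypts descending from that branch.  Given per-crypt
variant/total read counts for a mutation, the likelihood of placing it on
branch ``b`` is a product of binomials: carrier crypts (descendants of ``b``)
have expected VAF equal to the crypt's clonality (its median VAF), all other
crypts have expected VAF equal to a sequencing error rate.  Mutations whose
read-count pattern fits no branch — e.g. shared by crypts in disjoint clades —
are rejected by a likelihood-ratio adherence test.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


class CryptPhylogeny:
    """Rooted crypt tree with per-branch mutation annotations.

    Branches are identified by the node below them and numbered in post-order
    (children before parents), so terminal branches of early-listed leaves get
    the lowest ids and the root branch the highest.  Annotations
    (``mutations``, ``observed_count``, ``sensitivity``, ``adjusted_count``)
    are dictionaries keyed by branch id.
    """

    def __init__(self, tree: dendropy.Tree, patient_id: str = ""):
        tree.encode_bipartitions(suppress_unifurcations=False)
        self.tree = tree
        self.patient_id = patient_id
        self._nodes: dict[int, dendropy.Node] = {}
        self._crypts_below: dict[int, frozenset] = {}
        for i, node in enumerate(tree.postorder_node_iter()):
            node.branch_id = i
            self._nodes[i] = node
            if node.is_leaf():
                self._crypts_below[i] = frozenset([node.taxon.label])
            else:
                below = frozenset().union(
                    *(self._crypts_below[c.branch_id] for c in node.child_nodes())
                )
                self._crypts_below[i] = below
        self.mutations: dict[int, list] = {i: [] for i in self._nodes}
        self.observed_count: dict[int, float] = {}
        self.sensitivity: dict[int, float] = {}
        self.adjusted_count: dict[int, float] = {}

    # -- construction / serialization ------------------------------------
    @classmethod
    def from_newick(cls, source: str, patient_id: str = "") -> "CryptPhylogeny":
        """Parse a rooted Newick tree; ``source`` is a path or a Newick string."""
        if source.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=source, schema="newick", rooting="force-rooted")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick", rooting="force-rooted")
        return cls(tree, patient_id=patient_id)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)

    # -- structure queries -------------------------------------------------
    @property
    def crypts(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def branch_ids(self) -> list[int]:
        return sorted(self._nodes)

    def descendants(self, branch_id: int) -> frozenset:
        """Crypts descending from (carried by) a branch."""
        return self._crypts_below[branch_id]

    def branch_length(self, branch_id: int) -> float:
        el = self._nodes[branch_id].edge.length
        return 0.0 if el is None else float(el)

    def crypt_path(self, crypt: str) -> list[int]:
        """Branch ids on the root-to-leaf path of a crypt (root first)."""
        node = next(
            lf for lf in self.tree.leaf_node_iter() if lf.taxon.label == crypt
        )
        path = []
        while node is not None:
            path.append(node.branch_id)
            node = node.parent_node
        return path[::-1]

    # -- burdens -----------------------------------------------------------
    def crypt_totals(self, adjusted: bool = False) -> pd.Series:
        """Per-crypt mutation totals as path sums of branch counts."""
        counts = self.adjusted_count if adjusted else self.observed_count
        out = {}
        for crypt in self.crypts:
            out[crypt] = float(sum(counts.get(b, 0.0) for b in self.crypt_path(crypt)))
        return pd.Series(out, name="adjusted" if adjusted else "observed")

    def set_observed_from_mutations(self) -> None:
        self.observed_count = {b: float(len(m)) for b, m in self.mutations.items()}


class BranchAssigner(BaseEstimator):
    """Maximum-likelihood assignment of somatic mutations to tree branches.

    Parameters
    ----------
    error_rate : float
        Expected VAF in crypts that do not carry the mutation (sequencing
        noise), default 1e-3.
    alpha : float
        Adherence threshold: mutations whose best tree-constrained placement
        is worse than the best unconstrained crypt subset at p < alpha
        (likelihood-ratio test, chi2 with 1 df) are rejected, default 0.01.
    null : {"chi2", "bootstrap"}
        Reference distribution for the adherence statistic.
    n_boot : int
        Bootstrap replicates when ``null="bootstrap"``.

    Attributes
    ----------
    assignments_ : DataFrame with one row per mutation: site_id, branch_id,
        logl, logl_free, p_adherence, accepted, reason.
    rejected_ : list of site ids that were rejected.
    tree_ : the CryptPhylogeny with accepted mutations placed.
    """

    def __init__(self, error_rate: float = 1e-3, alpha: float = 0.01,
                 null: str = "chi2", n_boot: int = 200, random_state: int = 0):
        self.error_rate = error_rate
        self.alpha = alpha
        self.null = null
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, tree: CryptPhylogeny, matrix, site_ids: Iterable | None = None,
            clonality: Mapping[str, float] | None = None):
        crypts = list(matrix.crypts)
        if set(crypts) != set(tree.crypts):
            raise ValueError(
                f"tree/matrix crypt mismatch: {sorted(set(crypts) ^ set(tree.crypts))}"
            )
        if site_ids is None:
            site_ids = list(matrix.sites["site_id"])
        theta = np.array([
            0.5 if clonality is None else float(clonality[c]) for c in crypts
        ])
        err = max(self.error_rate, 0.0)

        branch_ids = sorted(
            tree.branch_ids, key=lambda b: (len(tree.descendants(b)), b)
        )
        carrier_masks = np.array([
            [c in tree.descendants(b) for c in crypts] for b in branch_ids
        ])
        rng = np.random.default_rng(self.random_state)

        rows = []
        site_index = {s: i for i, s in enumerate(matrix.sites["site_id"])}
        for sid in site_ids:
            i = site_index[sid]
            k = matrix.var[i].astype(float)
            n = matrix.dp[i].astype(float)
            lp_car = _binom_logpmf(k, n, theta)
            lp_non = _binom_logpmf(k, n, np.full_like(theta, err))
            branch_ll = np.where(carrier_masks, lp_car[None, :],
                                 lp_non[None, :]).sum(axis=1)
            best = int(np.argmax(branch_ll))
            logl = float(branch_ll[best])
            logl_free = float(np.maximum(lp_car, lp_non).sum())
            free_carriers = lp_car > lp_non
            if not free_carriers.any():
                rows.append((sid, -1, logl, logl_free, np.nan, False, "absent"))
                continue
            lr = max(0.0, 2.0 * (logl_free - logl))
            if self.null == "bootstrap":
                p = self._bootstrap_p(lr, n, theta, err,
                                      carrier_masks[best], carrier_masks, rng)
            else:
                p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
            ok = p >= self.alpha
            rows.append((
                sid, branch_ids[best] if ok else -1, logl, logl_free, p, ok,
                "" if ok else "non-tree-pattern",
            ))

        self.assignments_ = pd.DataFrame(
            rows, columns=["site_id", "branch_id", "logl", "logl_free",
                           "p_adherence", "accepted", "reason"],
        )
        self.rejected_ = list(self.assignments_.loc[~self.assignments_.accepted, "site_id"])
        for b in tree.mutations:
            tree.mutations[b] = []
        for _, r in self.assignments_[self.assignments_.accepted].iterrows():
            tree.mutations[int(r.branch_id)].append(r.site_id)
        tree.set_observed_from_mutations()
        self.tree_ = tree
        return self

    def _bootstrap_p(self, lr_obs, n, theta, err, best_mask, carrier_masks, rng):
        """Parametric-bootstrap null for the adherence statistic."""
        lrs = np.empty(self.n_boot)
        p_true = np.where(best_mask, theta, err)
        for b in range(self.n_boot):
            k = rng.binomial(n.astype(int), p_true).astype(float)
            lp_car = _binom_logpmf(k, n, theta)
            lp_non = _binom_logpmf(k, n, np.full_like(theta, err))
            gain = lp_car - lp_non
            ll = carrier_masks @ gain
            lrs[b] = 2.0 * (np.clip(gain, 0.0, None).sum() - ll.max())
        return float((np.sum(lrs >= lr_obs) + 1) / (self.n_boot + 1))


def _binom_logpmf(k, n, p):
    """Binomial log-pmf that treats p=0 exactly (0 successes -> prob 1)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = stats.binom.logpmf(k, n, np.clip(p, 1e-300, 1 - 1e-12))
    zero = p == 0
    if np.any(zero):
        out = np.where(zero, np.where(k == 0, 0.0, -np.inf), out)
    return out


def assign_mutations(tree, matrix, site_ids=None, clonality=None,
                     error_rate: float = 1e-3, alpha: float = 0.01):
    """Place mutations on branches; returns (tree, assignments, rejected)."""
    est = BranchAssigner(error_rate=error_rate, alpha=alpha)
    est.fit(tree, matrix, site_ids=site_ids, clonality=clonality)
    return est.tree_, est.assignments_, est.rejected_


def branch_burdens(tree: CryptPhylogeny, matrix=None, adjusted: bool = False):
    """Per-crypt totals and per-branch counts split by mutation class.

    Crypt totals are path sums of branch counts (observed, or sensitivity
    adjusted when ``adjusted=True``).  If a genotype matrix is given, branch
    counts are additionally split into SNV / indel.
    """
    totals = tree.crypt_totals(adjusted=adjusted)
    rows = []
    classes = None
    if matrix is not None:
        classes = dict(zip(matrix.sites["site_id"], matrix.sites["vclass"]))
    for b in tree.branch_ids:
        muts = tree.mutations.get(b, [])
        row = {"branch_id": b, "n_mutations": len(muts),
               "observed": tree.observed_count.get(b, float(len(muts))),
               "adjusted": tree.adjusted_count.get(b, np.nan),
               "n_crypts": len(tree.descendants(b))}
        if classes is not None:
            row["n_snv"] = sum(1 for m in muts if classes.get(m) == "SNV")
            row["n_indel"] = sum(1 for m in muts if classes.get(m) == "indel")
        rows.append(row)
    return totals, pd.DataFrame(rows)
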