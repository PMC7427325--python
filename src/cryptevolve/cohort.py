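"""Synthetic crypt cohorts with the full statistical structure of the analysis.

The generator emulates the sampling design of a laser-capture study of the
colonic epithelium: patients contribute biopsies, biopsies contribute
monoclonal crypts, and each crypt's somatic mutation burden follows

    E[burden] = age * age_rate + duration * disease_rate
                + patient deviation + biopsy deviation,

realized as Poisson counts distributed over the branches of a per-patient
genealogy (late clades confined to single biopsies, early splits in
development), so path sums reproduce each crypt's burden exactly in
expectation.  Controls and never-inflamed biopsies get disease duration zero.
Read counts, when requested, place germline variants in every crypt at VAF
0.5 (0.95 dosage on male sex chromosomes), somatic variants at the crypt's
clonality in carrier crypts only, and artifact sites scattered across crypts
with a low-overdispersion beta-binomial; depths are Poisson around the
crypt's median coverage.

Ground truth for every downstream stage (tree, branch counts, clonality,
sensitivity, site labels, generating coefficients) is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .filtering import GenotypeMatrix
from .phylo import CryptPhylogeny
from .signatures import SBS96, make_synthetic_signatures

CHROMS = [str(i) for i in range(1, 23)]


@dataclass
class CohortConfig:
    """Generative parameters; defaults are the fitted values of the study
    conditions this generator emulates (rates in mutations/crypt/year,
    SDs in mutations)."""

    n_patients_case: int = 40
    n_patients_control: int = 40
    biopsies_per_patient: int = 2
    crypts_per_biopsy: int = 5
    age_range: tuple = (20.0, 75.0)
    duration_range: tuple = (1.0, 30.0)
    age_sub_rate: float = 40.0
    disease_sub_rate: float = 55.0
    age_indel_rate: float = 1.0
    disease_indel_rate: float = 6.8
    sv_rate: float = 0.067
    patient_sd_case: float = 776.0
    patient_sd_control: float = 383.0
    biopsy_sd_case: float = 955.0
    biopsy_sd_control: float = 407.0
    indel_patient_sd_case: float = 80.0
    indel_patient_sd_control: float = 34.0
    indel_biopsy_sd_case: float = 81.0
    indel_biopsy_sd_control: float = 18.0
    smoking_sub_rate: float = 0.0
    smoking_indel_rate: float = 0.0
    smoking_range: tuple = (0.0, 30.0)
    driver_rate: float = 0.0
    driver_sub_effect: float = 0.0
    signature_rates: dict | None = None  # name -> (age part, disease part)
    mean_coverage: float = 18.2
    clonality_range: tuple = (0.38, 0.50)
    n_germline: int = 30
    n_artifact: int = 10
    artifact_rho: float = 0.01
    artifact_vaf: float = 0.05
    never_inflamed_fraction: float = 0.1
    biopsy_span_fraction: float = 1.0 / 19.0
    dev_epoch: float = 0.05  # fraction of molecular time before crypt fission
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_patients_case < 0 or self.n_patients_control < 0:
            raise ValueError("patient counts must be nonnegative")
        if self.n_patients_case + self.n_patients_control < 1:
            raise ValueError("cohort must contain at least one patient")
        for name in ("biopsies_per_patient", "crypts_per_biopsy"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("age_sub_rate", "disease_sub_rate", "age_indel_rate",
                     "disease_indel_rate", "sv_rate", "smoking_sub_rate",
                     "driver_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.clonality_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("clonality_range must lie in (0, 0.5]")
        if self.signature_rates is not None:
            ages = sum(v[0] for v in self.signature_rates.values())
            dis = sum(v[1] for v in self.signature_rates.values())
            if not np.isclose(ages, self.age_sub_rate, rtol=1e-6):
                raise ValueError("signature age rates must sum to age_sub_rate")
            if not np.isclose(dis, self.disease_sub_rate, rtol=1e-6):
                raise ValueError(
                    "signature disease rates must sum to disease_sub_rate"
                )
        return self


@dataclass
class SyntheticTruth:
    """Ground truth: trees, branch counts, clonality/sensitivity, labels."""

    trees: dict                    # patient -> CryptPhylogeny
    branch_counts: dict            # patient -> DataFrame (branch_id, subs, indels, ...)
    branch_spectra: dict           # patient -> DataFrame (branch x 96) or {}
    clonality: dict                # crypt -> fraction
    sensitivity: dict              # crypt -> fraction (support threshold 3)
    site_labels: dict              # patient -> Series site_id -> label
    burdens: pd.DataFrame          # per-crypt true burdens
    coefficients: dict             # the generating CohortConfig as a dict
    signatures: pd.DataFrame | None = None


def simulate_cohort(config: CohortConfig, genotypes: bool = True,
                    spectra: bool | None = None):
    """Generate a cohort; returns (matrices, metadata, truth).

    ``matrices`` maps patient id to a GenotypeMatrix (or is empty when
    ``genotypes=False``).  ``spectra`` (default: on iff signature_rates are
    configured) draws per-branch 96-channel substitution spectra from
    synthetic reference signatures.
    """
    config.validate()
    if spectra is None:
        spectra = config.signature_rates is not None
    if spectra and config.signature_rates is None:
        raise ValueError("spectra requested but no signature_rates configured")

    sig_defs = None
    if spectra:
        names = list(config.signature_rates)
        sig_defs = make_synthetic_signatures(
            len(names), seed=substream(config.seed, "sigdefs").integers(2**31),
            names=names,
        )

    matrices, meta_rows, burden_rows = {}, [], []
    trees, branch_counts, branch_spectra = {}, {}, {}
    clonality, sensitivity, site_labels = {}, {}, {}

    n_total = config.n_patients_case + config.n_patients_control
    for idx in range(n_total):
        cohort = "case" if idx < config.n_patients_case else "control"
        pid = f"P{idx + 1:03d}"
        rng = substream(config.seed, "patient", idx)
        out = _simulate_patient(pid, cohort, config, rng, genotypes, spectra,
                                sig_defs)
        trees[pid] = out["tree"]
        branch_counts[pid] = out["branch_counts"]
        if spectra:
            branch_spectra[pid] = out["spectra"]
        clonality.update(out["clonality"])
        sensitivity.update(out["sensitivity"])
        meta_rows.extend(out["meta"])
        burden_rows.extend(out["burdens"])
        if genotypes:
            matrices[pid] = out["matrix"]
            site_labels[pid] = out["labels"]

    metadata = pd.DataFrame(meta_rows)
    burdens = pd.DataFrame(burden_rows)
    truth = SyntheticTruth(
        trees=trees, branch_counts=branch_counts, branch_spectra=branch_spectra,
        clonality=clonality, sensitivity=sensitivity, site_labels=site_labels,
        burdens=burdens, coefficients=asdict(config), signatures=sig_defs,
    )
    return matrices, metadata, truth


def burden_table(metadata: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    """Crypt-level modelling table: metadata joined with true burdens."""
    return metadata.merge(truth.burdens, on="crypt", validate="1:1")


def _simulate_patient(pid, cohort, cfg, rng, genotypes, spectra, sig_defs):
    case = cohort == "case"
    sex = rng.choice(["male", "female"])
    age = rng.uniform(*cfg.age_range)
    duration = rng.uniform(*cfg.duration_range) if case else 0.0
    smoking = (rng.uniform(*cfg.smoking_range)
               if (cfg.smoking_sub_rate > 0 or cfg.smoking_indel_rate > 0) else 0.0)
    # Patient/biopsy deviations are mean-one lognormal factors whose SD at
    # the cohort's reference burden equals the configured SD in mutation
    # units; this keeps E[burden | age, duration] exactly on the linear
    # predictor (additive zero-mean Gaussians would need clipping at zero,
    # which lifts cohort means and biases the duration effect upward).
    ref_sub = _reference_mean(cfg, case, cfg.age_sub_rate, cfg.disease_sub_rate,
                              cfg.smoking_sub_rate)
    ref_ind = _reference_mean(cfg, case, cfg.age_indel_rate,
                              cfg.disease_indel_rate, cfg.smoking_indel_rate)
    f_pat_sub = _lognormal_factor(
        rng, (cfg.patient_sd_case if case else cfg.patient_sd_control), ref_sub)
    f_pat_ind = _lognormal_factor(
        rng, (cfg.indel_patient_sd_case if case else cfg.indel_patient_sd_control),
        ref_ind)

    biopsy_ids, crypts, crypt_biopsy = [], [], {}
    bio_dur, bio_loc, bio_inflamed, v_sub, v_ind = {}, {}, {}, {}, {}
    for b in range(cfg.biopsies_per_patient):
        bid = f"{pid}_B{b + 1}"
        biopsy_ids.append(bid)
        never = case and rng.random() < cfg.never_inflamed_fraction
        bio_inflamed[bid] = not never if case else False
        bio_dur[bid] = 0.0 if (never or not case) else duration
        bio_loc[bid] = rng.choice(["proximal", "distal", "rectum"])
        v_sub[bid] = f_pat_sub * _lognormal_factor(
            rng, cfg.biopsy_sd_case if case else cfg.biopsy_sd_control, ref_sub)
        v_ind[bid] = f_pat_ind * _lognormal_factor(
            rng, cfg.indel_biopsy_sd_case if case else cfg.indel_biopsy_sd_control,
            ref_ind)
        for k in range(cfg.crypts_per_biopsy):
            cid = f"{bid}_C{k + 1}"
            crypts.append(cid)
            crypt_biopsy[cid] = bid

    clon = {c: rng.uniform(*cfg.clonality_range) for c in crypts}
    cov = {c: max(8.0, rng.normal(cfg.mean_coverage, 1.5)) for c in crypts}
    drivers = {c: int(rng.poisson(cfg.driver_rate)) for c in crypts}

    tree = _random_tree(pid, {b: [c for c in crypts if crypt_biopsy[c] == b]
                              for b in biopsy_ids},
                        rng, cfg.biopsy_span_fraction, cfg.dev_epoch)

    # mean burdens, split into disease-attributable and the rest; the biopsy
    # factor scales both components so E[.] stays on the linear predictor
    dis_sub = {c: bio_dur[crypt_biopsy[c]] * cfg.disease_sub_rate
               * v_sub[crypt_biopsy[c]] for c in crypts}
    # the driver term stays outside the exposure factor: it is a per-crypt
    # fixed offset, not part of the patient's mutation-rate scaling
    base_sub = {c: (age * cfg.age_sub_rate + smoking * cfg.smoking_sub_rate)
                * v_sub[crypt_biopsy[c]]
                + drivers[c] * cfg.driver_sub_effect for c in crypts}
    dis_ind = {c: bio_dur[crypt_biopsy[c]] * cfg.disease_indel_rate
               * v_ind[crypt_biopsy[c]] for c in crypts}
    base_ind = {c: (age * cfg.age_indel_rate + smoking * cfg.smoking_indel_rate)
                * v_ind[crypt_biopsy[c]] for c in crypts}

    sub_counts = _branch_counts(tree, base_sub, dis_sub, rng)
    ind_counts = _branch_counts(tree, base_ind, dis_ind, rng)

    bc = pd.DataFrame({
        "branch_id": tree.branch_ids,
        "subs": [sub_counts["total"][b] for b in tree.branch_ids],
        "subs_disease": [sub_counts["disease"][b] for b in tree.branch_ids],
        "indels": [ind_counts["total"][b] for b in tree.branch_ids],
    })
    tree.observed_count = {
        b: float(sub_counts["total"][b] + ind_counts["total"][b])
        for b in tree.branch_ids
    }

    spectra_df, sig_branch = None, {}
    if spectra:
        spectra_df, sig_branch = _branch_spectra(tree, sub_counts, cfg, sig_defs, rng)

    meta, burdens = [], []
    for c in crypts:
        bid = crypt_biopsy[c]
        meta.append({
            "crypt": c, "patient": pid, "biopsy": bid, "cohort": cohort,
            "sex": sex, "age": age, "disease_duration": bio_dur[bid],
            "inflamed": bio_inflamed[bid], "location": bio_loc[bid],
            "smoking_duration": smoking, "driver_count": drivers[c],
            "median_coverage": cov[c],
        })
        path = tree.crypt_path(c)
        row = {
            "crypt": c,
            "subs_burden": int(sum(sub_counts["total"][b] for b in path)),
            "indel_burden": int(sum(ind_counts["total"][b] for b in path)),
            "sv_count": int(rng.poisson(cfg.sv_rate * bio_dur[bid])),
        }
        if spectra:
            for s in sig_defs.columns:
                row[f"sig_{s}"] = int(sum(sig_branch[b].get(s, 0) for b in path))
        burdens.append(row)

    sens = {c: float(stats.poisson.sf(2, cov[c] * clon[c])) for c in crypts}

    out = {
        "tree": tree, "branch_counts": bc, "spectra": spectra_df,
        "clonality": clon, "sensitivity": sens, "meta": meta, "burdens": burdens,
    }
    if genotypes:
        out["matrix"], out["labels"] = _genotype_matrix(
            pid, sex, tree, sub_counts["total"], ind_counts["total"],
            crypts, clon, cov, cfg, rng,
        )
    return out


def _reference_mean(cfg, case, age_rate, dis_rate, smoking_rate):
    """Cohort-level expected burden used to calibrate deviation factors."""
    mean_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    mean_dur = (0.5 * (cfg.duration_range[0] + cfg.duration_range[1])
                * (1 - cfg.never_inflamed_fraction)) if case else 0.0
    smoking_on = cfg.smoking_sub_rate > 0 or cfg.smoking_indel_rate > 0
    mean_smoke = 0.5 * (cfg.smoking_range[0] + cfg.smoking_range[1]) \
        if smoking_on else 0.0
    return mean_age * age_rate + mean_dur * dis_rate + mean_smoke * smoking_rate


def _lognormal_factor(rng, sd, ref_mean):
    """Mean-one lognormal factor with SD*ref_mean matching ``sd``."""
    if sd <= 0 or ref_mean <= 0:
        return 1.0
    s2 = np.log1p((sd / ref_mean) ** 2)
    return float(rng.lognormal(-s2 / 2.0, np.sqrt(s2)))


def _random_tree(pid, biopsy_crypts, rng, span_fraction, dev_epoch):
    """Random bifurcating genealogy: within-biopsy coalescent-style merges in
    (dev_epoch, 0.95), biopsy subtrees joined during development."""
    groups = {b: list(cs) for b, cs in biopsy_crypts.items()}
    bids = list(groups)
    # occasionally a clone spans two biopsies: move one crypt's lineage over
    if len(bids) > 1:
        for i in range(len(bids) - 1):
            if rng.random() < span_fraction and len(groups[bids[i]]) > 1:
                mover = groups[bids[i]].pop(int(rng.integers(len(groups[bids[i]]))))
                groups[bids[i + 1]].append(mover)

    taxa = dendropy.TaxonNamespace()
    subroots = []
    for b in bids:
        nodes = []
        for c in groups[b]:
            n = dendropy.Node()
            n.taxon = taxa.new_taxon(label=c)
            n._height = 1.0
            nodes.append(n)
        heights = np.sort(rng.uniform(dev_epoch, 0.95, size=len(nodes) - 1))[::-1]
        for h in heights:
            i, j = rng.choice(len(nodes), size=2, replace=False)
            parent = dendropy.Node()
            parent._height = float(h)
            for child in (nodes[i], nodes[j]):
                parent.add_child(child)
                child.edge.length = child._height - h
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        subroots.append(nodes[0])
    heights = np.sort(rng.uniform(0.01, dev_epoch, size=len(subroots) - 1))[::-1]
    nodes = subroots
    for h in heights:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        parent = dendropy.Node()
        parent._height = float(h)
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = child._height - h
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.edge.length = root._height  # truncal epoch since conception
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return CryptPhylogeny(tree, patient_id=pid)


def _branch_counts(tree, base, dis, rng):
    """Poisson branch counts whose path sums hit each crypt's mean exactly.

    Internal branches accrue mutations at clock rate over their epoch using
    the descendant-average mean; terminal branches absorb the remainder.
    Component means are floored at zero as a guard; with the multiplicative
    deviation factors they are nonnegative by construction.
    """
    leaf_ids = {next(iter(tree.descendants(b))): b for b in tree.branch_ids
                if len(tree.descendants(b)) == 1}
    total, disease = {}, {}
    acc_base = {c: 0.0 for c in base}  # internal mean already spent per crypt
    acc_dis = {c: 0.0 for c in base}
    internal = [b for b in tree.branch_ids if len(tree.descendants(b)) > 1]
    for b in internal:
        desc = tree.descendants(b)
        span = tree.branch_length(b)
        m_base = span * np.mean([max(0.0, base[c]) for c in desc])
        m_dis = span * np.mean([max(0.0, dis[c]) for c in desc])
        n_b = rng.poisson(m_base)
        n_d = rng.poisson(m_dis)
        total[b] = int(n_b + n_d)
        disease[b] = int(n_d)
        for c in desc:
            acc_base[c] += m_base
            acc_dis[c] += m_dis
    for c, b in leaf_ids.items():
        m_base = max(0.0, max(0.0, base[c]) - acc_base[c])
        m_dis = max(0.0, max(0.0, dis[c]) - acc_dis[c])
        n_b = rng.poisson(m_base)
        n_d = rng.poisson(m_dis)
        total[b] = int(n_b + n_d)
        disease[b] = int(n_d)
    return {"total": total, "disease": disease}


def _branch_spectra(tree, sub_counts, cfg, sig_defs, rng):
    """Split branch substitution counts across signatures, then channels."""
    names = list(cfg.signature_rates)
    w_age = np.array([cfg.signature_rates[s][0] for s in names], dtype=float)
    w_dis = np.array([cfg.signature_rates[s][1] for s in names], dtype=float)
    w_age = w_age / w_age.sum() if w_age.sum() > 0 else np.full(len(names), 1 / len(names))
    w_dis = w_dis / w_dis.sum() if w_dis.sum() > 0 else np.full(len(names), 1 / len(names))
    F = sig_defs.to_numpy()  # (96, S)
    rows, sig_branch = {}, {}
    for b in tree.branch_ids:
        n_tot = sub_counts["total"][b]
        n_dis = sub_counts["disease"][b]
        by_sig = rng.multinomial(n_tot - n_dis, w_age) + rng.multinomial(n_dis, w_dis)
        sig_branch[b] = pd.Series(by_sig, index=names)
        chan = np.zeros(len(SBS96), dtype=int)
        for s, n_s in enumerate(by_sig):
            if n_s:
                chan += rng.multinomial(n_s, F[:, s])
        rows[b] = chan
    spectra = pd.DataFrame(rows, index=SBS96).T
    return spectra, sig_branch


def _genotype_matrix(pid, sex, tree, sub_counts, ind_counts, crypts, clon, cov,
                     cfg, rng):
    sites, var_rows, dp_rows, labels = [], [], [], []
    n_crypts = len(crypts)
    clon_vec = np.array([clon[c] for c in crypts])
    cov_vec = np.array([cov[c] for c in crypts])
    sid = 0

    def depths():
        return rng.poisson(cov_vec)

    def add_site(chrom, ref, alt, vclass, var, dp, label):
        nonlocal sid
        sid += 1
        sites.append({"site_id": f"{pid}_s{sid}", "chrom": chrom,
                      "pos": int(rng.integers(1, 10_000_000)), "ref": ref,
                      "alt": alt, "vclass": vclass})
        var_rows.append(var)
        dp_rows.append(dp)
        labels.append(label)

    bases = np.array(list("ACGT"))
    # germline: every crypt, VAF 0.5; ~10% on X, hemizygous dosage in males
    n_x = max(1, cfg.n_germline // 10) if cfg.n_germline else 0
    for g in range(cfg.n_germline):
        on_x = g < n_x
        p0 = 0.95 if (on_x and sex == "male") else 0.5
        dp = depths()
        add_site("X" if on_x else rng.choice(CHROMS), *_snv_alleles(rng, bases),
                 "SNV", rng.binomial(dp, p0), dp, "germline")
    # somatic: one site per branch mutation, carried by descendant crypts
    carrier = {b: np.array([c in tree.descendants(b) for c in crypts])
               for b in tree.branch_ids}
    for b in tree.branch_ids:
        placed = []
        for counts, vclass in ((sub_counts, "SNV"), (ind_counts, "indel")):
            for _ in range(int(counts[b])):
                dp = depths()
                p = np.where(carrier[b], clon_vec, cfg.error_rate)
                ref, alt = _snv_alleles(rng, bases)
                if vclass == "indel":
                    alt = ref + "".join(rng.choice(bases, size=2))
                add_site(rng.choice(CHROMS), ref, alt, vclass,
                         rng.binomial(dp, p), dp, "somatic")
                placed.append(f"{pid}_s{sid}")
        tree.mutations[b] = placed
    # artifacts: low-mean beta-binomial scatter across crypts
    a = cfg.artifact_vaf * (1 - cfg.artifact_rho) / cfg.artifact_rho
    bb = (1 - cfg.artifact_vaf) * (1 - cfg.artifact_rho) / cfg.artifact_rho
    for _ in range(cfg.n_artifact):
        dp = depths()
        p = rng.beta(a, bb, size=n_crypts)
        add_site(rng.choice(CHROMS), *_snv_alleles(rng, bases), "SNV",
                 rng.binomial(dp, p), dp, "artifact")

    site_df = pd.DataFrame(sites)
    matrix = GenotypeMatrix(pid, site_df, np.array(var_rows), np.array(dp_rows),
                            list(crypts), sex)
    label_s = pd.Series(labels, index=site_df["site_id"].to_numpy(), name="label")
    return matrix, label_s


def _snv_alleles(rng, bases):
    ref = rng.choice(bases)
    alt = rng.choice([b for b in bases if b != ref])
    return str(ref), str(alt)


def simulate_duplicates(crypt: str, per_call_sensitivity: float, n_sites: int,
                        seed: int = 0) -> tuple[int, int]:
    """Duplicate-dissection experiment: detect each of n_sites true mutations
    independently in two replicates; returns (n1 seen once, n2 seen in both).
    Mutations missed by both replicates go unobserved."""
    if not 0 < per_call_sensitivity <= 1:
        raise ValueError("per_call_sensitivity must be in (0, 1]")
    rng = substream(seed, "duplicates", crypt)
    d1 = rng.random(n_sites) < per_call_sensitivity
    d2 = rng.random(n_sites) < per_call_sensitivity
    n2 = int(np.sum(d1 & d2))
    n1 = int(np.sum(d1 ^ d2))
    return n1, n2
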