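"""End-to-end orchestration: simulate / filter / assign / adjust / model.

``run_pipeline`` wires the stages in dependency order over files produced by
the simulator (or equivalent real inputs): per-patient genotype matrices,
crypt metadata, and rooted trees.  Stages never mutate each other's outputs;
every table is written fresh into the run directory together with a
provenance record (package version, resolved configuration and its hash).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .burden import fit_burden_lmm, fit_sv_rate, lrt_duration
from .cohort import CohortConfig, burden_table, simulate_cohort
from .filtering import BetaBinomialFilter
from .phylo import BranchAssigner, branch_burdens
from .sensitivity import TruncatedBinomialClonality, adjust_counts, crypt_sensitivity
from .signatures import SignatureEM, signature_burdens


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a pipeline run.

    Thresholds default to the analysis' standard values: somatic q < 1e-3
    (1e-2 under five crypts), overdispersion rho >= 0.1, >= 3 variant reads
    at depth >= 5, branches with > 50 mutations as signature samples, and
    the > 10% reconstitution rule.
    """

    in_dir: str = "."
    out_dir: str = "run"
    signatures_path: str | None = None
    q_threshold: float = 1e-3
    q_threshold_few: float = 1e-2
    rho_threshold: float = 0.1
    min_var_reads: int = 3
    min_depth: int = 5
    min_branch_mutations: int = 50
    min_fraction: float = 0.10
    error_rate: float = 1e-3
    adherence_alpha: float = 0.01
    sensitivity_min_reads: int = 3
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> Path:
    """Run filtering, placement, sensitivity adjustment, optional signature
    attribution and the burden models; returns the run directory."""
    ind = Path(config.in_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    meta_path = ind / "meta.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata: {meta_path}")
    meta = pd.read_csv(meta_path, sep="\t")
    patients = sorted(meta["patient"].unique())

    signatures = None
    if config.signatures_path:
        signatures = cio.read_signatures(config.signatures_path)

    crypt_rows = []
    stage_log = []
    for pid in patients:
        mpath = ind / f"matrix_{pid}.tsv"
        tpath = ind / f"tree_{pid}.nwk"
        for p in (mpath, tpath):
            if not p.exists():
                raise FileNotFoundError(f"missing input: {p}")
        matrix = cio.read_genotype_matrix(mpath)
        tree = cio.read_newick(tpath, patient_id=pid)
        pmeta = meta[meta["patient"] == pid].set_index("crypt")
        missing = set(matrix.crypts) ^ set(tree.crypts)
        if missing:
            raise ValueError(f"{pid}: crypt id mismatch {sorted(missing)}")

        filt = BetaBinomialFilter(
            q_threshold=config.q_threshold, q_threshold_few=config.q_threshold_few,
            rho_threshold=config.rho_threshold, min_var_reads=config.min_var_reads,
            min_depth=config.min_depth,
        ).fit(matrix)
        verdicts = filt.verdicts_
        cio.write_verdicts(verdicts, filt.presence_, out / f"verdicts_{pid}.tsv")
        cio.write_verdict_vcf(matrix, verdicts, out / f"filtered_{pid}.vcf")
        stage_log.append({"patient": pid, "stage": "filter",
                          **verdicts["classification"].value_counts().to_dict()})

        somatic = list(verdicts.index[verdicts["classification"] == "somatic"])
        idx = {s: i for i, s in enumerate(matrix.sites["site_id"])}
        clon, ss = {}, {}
        for c in matrix.crypts:
            j = matrix.crypts.index(c)
            k = matrix.var[[idx[s] for s in somatic], j]
            n = matrix.dp[[idx[s] for s in somatic], j]
            est = TruncatedBinomialClonality(
                truncation=config.min_var_reads
            )
            try:
                est.fit(k, n)
                clon[c] = est.vaf_
            except ValueError:
                clon[c] = 0.44
            ss[c] = crypt_sensitivity(
                clon[c], float(pmeta.loc[c, "median_coverage"]),
                min_mut_reads=config.sensitivity_min_reads,
            )

        assigner = BranchAssigner(error_rate=config.error_rate,
                                  alpha=config.adherence_alpha)
        assigner.fit(tree, matrix, site_ids=somatic, clonality=clon)
        assigner.assignments_.to_csv(out / f"assignments_{pid}.tsv", sep="\t",
                                     index=False)
        adjust_counts(tree, ss)
        totals_obs, per_branch = branch_burdens(tree, matrix)
        totals_adj = tree.crypt_totals(adjusted=True)
        per_branch.to_csv(out / f"branches_{pid}.tsv", sep="\t", index=False)
        cio.write_newick(tree, out / f"tree_adjusted_{pid}.nwk")

        classes = dict(zip(matrix.sites["site_id"], matrix.sites["vclass"]))
        for c in matrix.crypts:
            path = tree.crypt_path(c)
            adj_snv = sum(
                sum(1 for m in tree.mutations[b] if classes[m] == "SNV")
                / tree.sensitivity[b] for b in path
            )
            adj_ind = sum(
                sum(1 for m in tree.mutations[b] if classes[m] == "indel")
                / tree.sensitivity[b] for b in path
            )
            crypt_rows.append({
                "crypt": c, "patient": pid,
                "biopsy": pmeta.loc[c, "biopsy"],
                "cohort": pmeta.loc[c, "cohort"],
                "age": pmeta.loc[c, "age"],
                "disease_duration": pmeta.loc[c, "disease_duration"],
                "location": pmeta.loc[c, "location"],
                "median_coverage": pmeta.loc[c, "median_coverage"],
                "clonality": clon[c], "sensitivity": ss[c],
                "observed_burden": float(totals_obs[c]),
                "adjusted_burden": float(totals_adj[c]),
                "subs_burden": adj_snv, "indel_burden": adj_ind,
            })

        if signatures is not None and (ind / "genome.fa").exists():
            import pyfaidx

            from .signatures import build_spectra

            fasta = pyfaidx.Fasta(str(ind / "genome.fa"))
            spectra = build_spectra(tree, matrix, fasta,
                                    min_branch_mutations=config.min_branch_mutations)
            if len(spectra):
                em = SignatureEM(signatures).fit(spectra)
                em.exposures_.to_csv(out / f"exposures_{pid}.tsv", sep="\t")

    crypts = pd.DataFrame(crypt_rows)
    crypts.to_csv(out / "crypts.tsv", sep="\t", index=False)

    fits = {}
    try:
        fit = fit_burden_lmm(crypts, response="subs_burden",
                             fixed=("age", "disease_duration"))
        stat, dof, p = lrt_duration(crypts, response="subs_burden")
        fits["substitutions"] = _fit_json(fit) | {
            "lrt_duration": {"statistic": stat, "df": dof, "p": p}}
    except Exception as e:  # tiny fixtures may not support a full fit
        fits["substitutions"] = {"error": str(e)}

    resolved = dataclasses.asdict(config)
    provenance = {"version": __version__, "config": resolved,
                  "config_hash": cio.config_hash(resolved)}
    report = {"provenance": provenance, "fits": fits,
              "stage_log": stage_log, "n_crypts": len(crypts)}
    (out / "fit.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                             default=float))
    return out


def _fit_json(fit) -> dict:
    return {
        "coefficients": {
            term: {"estimate": float(r["estimate"]),
                   "ci95": [float(r["lo"]), float(r["hi"])]}
            for term, r in fit.coef.iterrows()
        },
        "variance_components": {k: float(v) for k, v in
                                fit.variance_components.items()},
        "loglik": fit.loglik, "converged": fit.converged,
    }


def write_simulation(config: CohortConfig, out_dir, genotypes: bool = True):
    """Simulate a cohort and write it in the pipeline's input layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, meta, truth = simulate_cohort(config, genotypes=genotypes)
    meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    burden_table(meta, truth).to_csv(out / "burdens_true.tsv", sep="\t",
                                     index=False)
    for pid, tree in truth.trees.items():
        cio.write_newick(tree, out / f"tree_{pid}.nwk")
    for pid, matrix in matrices.items():
        cio.write_genotype_matrix(matrix, out / f"matrix_{pid}.tsv")
    labels = {p: s.to_dict() for p, s in truth.site_labels.items()}
    resolved = dataclasses.asdict(config)
    (out / "truth.json").write_text(json.dumps({
        "config": resolved, "config_hash": cio.config_hash(resolved),
        "version": __version__, "site_labels": labels,
        "clonality": truth.clonality, "sensitivity": truth.sensitivity,
    }, indent=2, sort_keys=True, default=float))
    return matrices, meta, truth
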