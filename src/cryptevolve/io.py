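"""Readers and writers for the pipeline's file formats.

Formats are plain text: genotype matrices as TSV with per-crypt "var:depth"
columns, multi-sample VCF with AD/DP (read via cyvcf2, written as text),
Newick trees, reference-signature TSVs and YAML configuration.  Coordinates
are 1-based throughout (VCF convention); indels are left-aligned with the
anchor base included.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .filtering import GenotypeMatrix
from .phylo import CryptPhylogeny
from .signatures import read_signatures, write_signatures  # noqa: F401  re-export

FIXED_COLS = ["site_id", "chrom", "pos", "ref", "alt", "vclass"]


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    df = matrix.sites[FIXED_COLS].copy()
    for j, crypt in enumerate(matrix.crypts):
        df[crypt] = [f"{v}:{d}" for v, d in zip(matrix.var[:, j], matrix.dp[:, j])]
    with open(path, "w") as fh:
        fh.write(f"##patient={matrix.patient_id}\n##sex={matrix.sex}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genotype_matrix(path) -> GenotypeMatrix:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("##"):
            key, _, val = line[2:].strip().partition("=")
            meta[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    missing = [c for c in FIXED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    crypts = [c for c in df.columns if c not in FIXED_COLS]
    try:
        var = df[crypts].map(lambda s: int(str(s).split(":")[0])).to_numpy()
        dp = df[crypts].map(lambda s: int(str(s).split(":")[1])).to_numpy()
    except (IndexError, ValueError) as e:
        raise ValueError(f"{path}: malformed var:depth cell ({e})") from None
    return GenotypeMatrix(meta.get("patient", Path(path).stem), df[FIXED_COLS],
                          var, dp, crypts, meta.get("sex", "female"))


def read_vcf_matrix(path, patient_id: str | None = None,
                    sex: str = "female") -> GenotypeMatrix:
    """Multi-sample VCF with per-sample AD (ref,alt depths) or DP."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    crypts = list(vcf.samples)
    sites, var_rows, dp_rows = [], [], []
    for i, v in enumerate(vcf):
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {v.CHROM}:{v.POS} lacks AD")
        ad = np.where(ad < 0, 0, ad)
        alt = ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(crypts), dtype=int)
        dp = ad.sum(axis=1)
        vclass = "SNV" if len(v.REF) == 1 and len(v.ALT[0]) == 1 else "indel"
        sites.append({"site_id": v.ID or f"s{i + 1}", "chrom": v.CHROM,
                      "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
                      "vclass": vclass})
        var_rows.append(alt)
        dp_rows.append(dp)
    return GenotypeMatrix(patient_id or Path(path).stem, pd.DataFrame(sites),
                          np.array(var_rows, dtype=int),
                          np.array(dp_rows, dtype=int), crypts, sex)


def write_verdict_vcf(matrix: GenotypeMatrix, verdicts: pd.DataFrame, path) -> None:
    """Filtered VCF with FILTER tags GERMLINE / ARTIFACT / LOW_SUPPORT."""
    tags = {"germline": "GERMLINE", "artifact": "ARTIFACT",
            "low_support": "LOW_SUPPORT", "somatic": "PASS"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=GERMLINE,Description="Germline by aggregated binomial test">\n')
        fh.write('##FILTER=<ID=ARTIFACT,Description="Beta-binomial overdispersion below threshold">\n')
        fh.write('##FILTER=<ID=LOW_SUPPORT,Description="Insufficient read support">\n')
        fh.write('##INFO=<ID=QGERM,Number=1,Type=Float,Description="Germline-test q-value">\n')
        fh.write('##INFO=<ID=RHO,Number=1,Type=Float,Description="Beta-binomial overdispersion ML">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.crypts) + "\n")
        for i, row in matrix.sites.iterrows():
            sid = row["site_id"]
            vd = verdicts.loc[sid]
            info = []
            if np.isfinite(vd.get("q_germline", np.nan)):
                info.append(f"QGERM={vd['q_germline']:.3g}")
            if np.isfinite(vd.get("rho_hat", np.nan)):
                info.append(f"RHO={vd['rho_hat']:.3g}")
            cells = "\t".join(
                f"{d - v},{v}:{d}" for v, d in zip(matrix.var[i], matrix.dp[i])
            )
            fh.write(f"{row['chrom']}\t{row['pos']}\t{sid}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t{tags[vd['classification']]}\t"
                     f"{';'.join(info) or '.'}\tAD:DP\t{cells}\n")


def write_verdicts(verdicts: pd.DataFrame, presence: pd.DataFrame, path) -> None:
    out = verdicts.copy()
    for c in presence.columns:
        out[f"present_{c}"] = presence[c].astype(int)
    out.to_csv(path, sep="\t", index_label="site_id")


def read_newick(path, patient_id: str = "") -> CryptPhylogeny:
    return CryptPhylogeny.from_newick(str(path), patient_id=patient_id)


def write_newick(tree: CryptPhylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(obj) -> str:
    """Stable hash of a resolved configuration for provenance records."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
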