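"""Parameter-recovery experiments: simulate at the generating rates, refit.

Each experiment simulates cohorts under the generator's default study-scale
conditions (40 case + 40 control patients, 2 biopsies x 5 crypts, ages 20-75,
disease durations 1-30 y) and re-estimates the generating coefficients with
the package's own models, replicate by replicate.  Medians over replicates
are the quantities a calibration study would report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .burden import fit_burden_lmm, fit_sv_rate
from .cohort import CohortConfig, burden_table, simulate_cohort
from .signatures import SignatureEM, signature_burdens

# disease-rate split across the three ubiquitous colon signatures
SIGNATURE_RATES = {"SBS1": (10.0, 13.0), "SBS5": (25.0, 23.0),
                   "SBS18": (5.0, 9.0)}


def _rep_seed(seed: int, label: str, i: int) -> int:
    h = np.random.SeedSequence([seed, sum(map(ord, label)), i])
    return int(h.generate_state(1)[0] % (2**31))


def recover_burden_effects(n_reps: int = 20, seed: int = 1,
                           smoking: bool = False) -> pd.DataFrame:
    """Per-replicate estimates of the substitution / indel / CNV effects.

    Returns one row per replicate with columns age_sub, dis_sub, age_ind,
    dis_ind, sv_rate (and smoke_sub when ``smoking``).
    """
    rows = []
    for i in range(n_reps):
        kwargs = dict(seed=_rep_seed(seed, "burden", i))
        if smoking:
            kwargs["smoking_sub_rate"] = 49.0
            kwargs["smoking_indel_rate"] = 5.3
        cfg = CohortConfig(**kwargs)
        _, meta, truth = simulate_cohort(cfg, genotypes=False)
        df = burden_table(meta, truth)
        fixed = ["age", "disease_duration", "location"]
        if smoking:
            fixed.append("smoking_duration")
        fit_s = fit_burden_lmm(df, response="subs_burden", fixed=tuple(fixed))
        fit_i = fit_burden_lmm(df, response="indel_burden", fixed=tuple(fixed))
        row = {
            "age_sub": fit_s.coef.loc["age", "estimate"],
            "dis_sub": fit_s.coef.loc["disease_duration", "estimate"],
            "age_ind": fit_i.coef.loc["age", "estimate"],
            "dis_ind": fit_i.coef.loc["disease_duration", "estimate"],
        }
        if smoking:
            row["smoke_sub"] = fit_s.coef.loc["smoking_duration", "estimate"]
            row["smoke_ind"] = fit_i.coef.loc["smoking_duration", "estimate"]
        else:
            fit_sv = fit_sv_rate(df)
            row["sv_rate"] = fit_sv.coef.loc["rate", "estimate"]
        rows.append(row)
    return pd.DataFrame(rows)


def recover_signature_effects(n_reps: int = 20, seed: int = 1,
                              min_branch_mutations: int = 50) -> pd.DataFrame:
    """End-to-end signature experiment: branch spectra -> EM exposures ->
    crypt signature burdens -> per-signature LMM disease coefficients."""
    names = list(SIGNATURE_RATES)
    rows = []
    for i in range(n_reps):
        cfg = CohortConfig(
            age_sub_rate=sum(v[0] for v in SIGNATURE_RATES.values()),
            disease_sub_rate=sum(v[1] for v in SIGNATURE_RATES.values()),
            signature_rates=SIGNATURE_RATES,
            seed=_rep_seed(seed, "signatures", i),
        )
        _, meta, truth = simulate_cohort(cfg, genotypes=False)
        df = burden_table(meta, truth)
        parts = []
        for pid, spectra in truth.branch_spectra.items():
            tree = truth.trees[pid]
            bc = truth.branch_counts[pid].set_index("branch_id")
            tree.observed_count = {b: float(bc.loc[b, "subs"])
                                   for b in tree.branch_ids}
            big = spectra.index[spectra.sum(axis=1) > min_branch_mutations]
            em = SignatureEM(truth.signatures).fit(spectra.loc[big])
            parts.append(signature_burdens(em.exposures_, tree,
                                           small_branch="inherit"))
        sigb = pd.concat(parts)
        sigb.index.name = "crypt"
        mdl = df.merge(sigb.reset_index(), on="crypt")
        row = {}
        for s in names:
            fit = fit_burden_lmm(mdl, response=s,
                                 fixed=("age", "disease_duration"))
            row[s] = fit.coef.loc["disease_duration", "estimate"]
        rows.append(row)
    return pd.DataFrame(rows)
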