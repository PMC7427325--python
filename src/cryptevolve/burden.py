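"""Mixed-effects models for mutation burden and structural-variant rates.

Per-crypt burdens are regressed on age and disease duration with a linear
mixed model whose structure mirrors the sampling design:

* fixed effects for age and disease duration (optionally colon location,
  coverage, smoking duration, driver count) — all in mutations per crypt per
  unit of the covariate;
* **no intercept**: most embryonic mutations are filtered with the germline,
  so the expected burden at birth is zero;
* nested random deviations for patient and for biopsy-within-patient, with
  separate variance parameters per cohort (cases vary in disease duration,
  extent and severity; controls do not), fitted by maximum likelihood so that
  nested models can be compared with likelihood-ratio tests.

Structural variants are few, so their counts are modelled with a mixed
Poisson regression whose mean is linear in disease duration
(``rate * duration``), making the coefficient directly an events/crypt/year
rate; an optional patient-level log-normal frailty captures between-patient
heterogeneity and is integrated out by Gauss-Hermite quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "BurdenFit", "BurdenLMM", "PoissonRateModel", "fit_burden_lmm",
    "lrt_duration", "variance_heterogeneity_test", "fit_sv_rate",
    "driver_association",
]

LOCATION_LEVELS = ("proximal", "distal", "rectum")


@dataclass
class BurdenFit:
    """Fitted coefficients, Wald 95% CIs, variance components and log-likelihood."""

    coef: pd.DataFrame  # columns: estimate, se, lo, hi
    variance_components: dict
    loglik: float
    converged: bool
    n_obs: int
    extras: dict = field(default_factory=dict)

    def __getitem__(self, term):
        return self.coef.loc[term]


class BurdenLMM(BaseEstimator):
    """Zero-intercept LMM with cohort-specific nested random effects.

    Parameters
    ----------
    response : str
        Column of the crypt table to model.
    fixed : sequence of str
        Fixed-effect terms; "location" expands into treatment-coded dummies
        (reference level proximal) without an intercept.
    cohort_specific : {"both", "patient", "biopsy", "none"}
        Which random-effect variances get separate case/control parameters.
    reml : bool
        Default False (ML), required for likelihood-ratio testing.

    Attributes (after fit)
    ----------
    fit_ : BurdenFit; result_ : statsmodels MixedLMResults.
    """

    def __init__(self, response: str = "subs_burden",
                 fixed=("age", "disease_duration"),
                 cohort_specific: str = "both", reml: bool = False):
        self.response = response
        self.fixed = fixed
        self.cohort_specific = cohort_specific
        self.reml = reml

    def fit(self, data: pd.DataFrame):
        import statsmodels.formula.api as smf

        df, exog_cols = _prepare(data, self.response, self.fixed)
        vc = {}
        both = df["is_case"].var() > 0 and df["is_ctrl"].var() > 0
        if both and self.cohort_specific in ("both", "patient"):
            vc["pat_case"] = "0 + is_case"
            vc["pat_ctrl"] = "0 + is_ctrl"
        else:
            vc["pat"] = "0 + one"
        if both and self.cohort_specific in ("both", "biopsy"):
            vc["bio_case"] = "0 + C(bwp):is_case"
            vc["bio_ctrl"] = "0 + C(bwp):is_ctrl"
        else:
            vc["bio"] = "0 + C(bwp)"

        formula = "_y ~ 0 + " + " + ".join(exog_cols)
        model = smf.mixedlm(formula, df, groups=df["patient"], vc_formula=vc,
                            re_formula="0")
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            last_err = None
            for method in ("lbfgs", "powell", "cg"):
                try:
                    res = model.fit(reml=self.reml, method=method, maxiter=2000)
                except (np.linalg.LinAlgError, ValueError) as e:
                    last_err = e
                    continue
                if res.converged:
                    break
            if res is None:
                raise RuntimeError(f"mixed model fit failed: {last_err}")

        params = res.fe_params
        se = res.bse_fe
        z = stats.norm.ppf(0.975)
        coef = pd.DataFrame({
            "estimate": params, "se": se,
            "lo": params - z * se, "hi": params + z * se,
        })
        vcomp = {name: float(v) for name, v in
                 zip(model.exog_vc.names, np.asarray(res.vcomp))}
        sds = {f"sd_{k}": float(np.sqrt(max(v, 0.0))) for k, v in vcomp.items()}
        sds["sd_residual"] = float(np.sqrt(res.scale))
        self.result_ = res
        self.fit_ = BurdenFit(
            coef=coef, variance_components={**vcomp, **sds},
            loglik=float(res.llf), converged=bool(res.converged),
            n_obs=int(len(df)),
        )
        if not res.converged:
            warnings.warn("mixed model did not converge; estimates reported anyway")
        return self


def _prepare(data: pd.DataFrame, response: str, fixed) -> tuple[pd.DataFrame, list]:
    df = data.copy()
    needed = {response, "patient", "biopsy", "cohort"} | (
        set(fixed) - {"location"}
    )
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df[list(needed)].isna().any().any():
        raise ValueError("missing values in model columns")
    df["_y"] = df[response].astype(float)
    df["is_case"] = (df["cohort"] == "case").astype(float)
    df["is_ctrl"] = 1.0 - df["is_case"]
    df["one"] = 1.0
    # biopsy index within patient keeps the vc design narrow
    df["bwp"] = df.groupby("patient")["biopsy"].transform(
        lambda s: pd.factorize(s)[0]
    ).astype(str)
    exog_cols = []
    for term in fixed:
        if term == "location":
            for lev in LOCATION_LEVELS[1:]:
                col = f"loc_{lev}"
                df[col] = (df["location"] == lev).astype(float)
                exog_cols.append(col)
        else:
            if df[term].astype(float).var() == 0:
                raise ValueError(f"covariate {term!r} has zero variance")
            exog_cols.append(term)
    return df, exog_cols


def fit_burden_lmm(data: pd.DataFrame, response: str = "subs_burden",
                   fixed=("age", "disease_duration"),
                   cohort_specific: str = "both") -> BurdenFit:
    """ML fit of the zero-intercept nested LMM; returns a BurdenFit."""
    est = BurdenLMM(response=response, fixed=fixed,
                    cohort_specific=cohort_specific).fit(data)
    return est.fit_


def lrt_duration(data: pd.DataFrame, response: str = "subs_burden",
                 fixed=("age", "disease_duration"),
                 term: str = "disease_duration") -> tuple[float, int, float]:
    """LRT for a fixed term: (chi-square statistic, df, two-sided p)."""
    if term not in fixed:
        raise ValueError(f"{term!r} not among the fixed effects {fixed}")
    full = fit_burden_lmm(data, response=response, fixed=fixed)
    reduced = fit_burden_lmm(data, response=response,
                             fixed=tuple(t for t in fixed if t != term))
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df=1))
    return stat, 1, p


def variance_heterogeneity_test(data: pd.DataFrame,
                                response: str = "subs_burden",
                                fixed=("age", "disease_duration")) -> pd.DataFrame:
    """LRT for cohort differences in patient- and biopsy-level SDs.

    One level at a time: the model with separate case/control variances at
    that level (the other level stays cohort-specific) is compared against
    the model with a pooled variance there.  Returns one row per level with
    both SD estimates and the p-value.
    """
    full = BurdenLMM(response=response, fixed=fixed,
                     cohort_specific="both").fit(data).fit_
    rows = []
    for level, pooled_mode, keys in (
        ("patient", "biopsy", ("sd_pat_case", "sd_pat_ctrl")),
        ("biopsy", "patient", ("sd_bio_case", "sd_bio_ctrl")),
    ):
        pooled = BurdenLMM(response=response, fixed=fixed,
                           cohort_specific=pooled_mode).fit(data).fit_
        stat = max(0.0, 2.0 * (full.loglik - pooled.loglik))
        rows.append({
            "level": level,
            "sd_case": full.variance_components.get(keys[0], np.nan),
            "sd_control": full.variance_components.get(keys[1], np.nan),
            "statistic": stat, "df": 1,
            "p": float(stats.chi2.sf(stat, df=1)),
        })
    return pd.DataFrame(rows)


def driver_association(data: pd.DataFrame, response: str = "subs_burden",
                       fixed=("age", "disease_duration")) -> BurdenFit:
    """Effect of per-crypt driver count on burden (mutations per driver)."""
    return fit_burden_lmm(data, response=response,
                          fixed=tuple(fixed) + ("driver_count",))


class PoissonRateModel(BaseEstimator):
    """Mixed Poisson regression with mean linear in disease duration.

    mean_ij = rate * duration_ij (+ baseline if requested), multiplied by a
    patient-level log-normal frailty exp(u_i), u_i ~ N(0, sigma^2), when
    ``random_effects`` is on.  The frailty is integrated out with
    Gauss-Hermite quadrature; with it off and no baseline the ML estimate is
    the closed form sum(counts) / sum(durations).

    Attributes
    ----------
    rate_, rate_ci_ : events/crypt/year and Wald 95% CI.
    years_per_event_ : 1 / rate_.
    sigma_, baseline_, loglik_ : nuisance parameters and fitted ML.
    """

    def __init__(self, response: str = "sv_count",
                 duration_col: str = "disease_duration",
                 baseline: bool = False, random_effects: bool = True,
                 n_quad: int = 25):
        self.response = response
        self.duration_col = duration_col
        self.baseline = baseline
        self.random_effects = random_effects
        self.n_quad = n_quad

    def fit(self, data: pd.DataFrame):
        y = data[self.response].to_numpy(dtype=float)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("counts must be nonnegative integers")
        d = data[self.duration_col].to_numpy(dtype=float)
        groups = pd.factorize(data["patient"])[0]
        nodes, wts = np.polynomial.hermite.hermgauss(self.n_quad)
        self._gh = (nodes, wts / np.sqrt(np.pi))

        def unpack(theta):
            rate = theta[0]
            b0 = theta[1] if self.baseline else 0.0
            sig = theta[-1] if self.random_effects else 0.0
            return rate, b0, sig

        def nll(theta):
            ll = self._loglik(y, d, groups, *unpack(theta))
            return -ll if np.isfinite(ll) else 1e12

        denom = d.sum()
        r0 = y.sum() / denom if denom > 0 else 0.0
        x0, bounds = [max(r0, 1e-6)], [(0.0, None)]
        if self.baseline:
            x0 += [max(y.mean() * 0.1, 1e-6)]
            bounds += [(0.0, None)]
        if self.random_effects:
            x0 += [0.3]
            bounds += [(1e-8, 5.0)]
        res = optimize.minimize(nll, np.asarray(x0), method="L-BFGS-B",
                                bounds=bounds)
        rate, b0, sig = unpack(res.x)
        self.rate_ = float(rate)
        self.baseline_ = float(b0)
        self.sigma_ = float(sig)
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success)
        se = self._rate_se(res.x, nll)
        z = stats.norm.ppf(0.975)
        self.rate_se_ = se
        self.rate_ci_ = (max(0.0, rate - z * se), rate + z * se)
        self.years_per_event_ = float(np.inf if rate == 0 else 1.0 / rate)
        return self

    def _loglik(self, y, d, groups, rate, b0, sigma):
        mu = b0 + rate * d
        if sigma <= 1e-8:
            return float(_pois_logpmf(y, mu).sum())
        nodes, w = self._gh
        total = 0.0
        for g in np.unique(groups):
            sel = groups == g
            # (n_quad, n_crypts): per-node log-density with frailty exp(s*node)
            scale = np.exp(np.sqrt(2.0) * sigma * nodes)[:, None]
            lp = _pois_logpmf(y[sel][None, :], mu[sel][None, :] * scale).sum(axis=1)
            m = lp.max()
            if not np.isfinite(m):
                return -np.inf
            total += m + np.log(np.clip((w * np.exp(lp - m)).sum(), 1e-300, None))
        return float(total)

    def _rate_se(self, theta, nll):
        h = max(1e-5, 1e-4 * max(theta[0], 1e-3))
        tp, tm = theta.copy(), theta.copy()
        tp[0] += h
        tm[0] = max(tm[0] - h, 0.0)
        f0, fp, fm = nll(theta), nll(tp), nll(tm)
        d2 = (fp - 2 * f0 + fm) / ((tp[0] - theta[0]) * (theta[0] - tm[0]) or h * h)
        return float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan

    def lrt(self, data: pd.DataFrame) -> tuple[float, int, float]:
        """LRT for the duration term (baseline-augmented nesting)."""
        alt = PoissonRateModel(self.response, self.duration_col, baseline=True,
                               random_effects=self.random_effects,
                               n_quad=self.n_quad).fit(data)
        null = _BaselineOnlyPoisson(self.response,
                                    random_effects=self.random_effects,
                                    n_quad=self.n_quad).fit(data)
        stat = max(0.0, 2.0 * (alt.loglik_ - null.loglik_))
        return stat, 1, float(stats.chi2.sf(stat, df=1))


class _BaselineOnlyPoisson(PoissonRateModel):
    """Null model for the duration LRT: constant mean, no rate term."""

    def __init__(self, response, random_effects=True, n_quad=25):
        super().__init__(response=response, duration_col="_zero",
                         baseline=True, random_effects=random_effects,
                         n_quad=n_quad)

    def fit(self, data):
        data = data.copy()
        data["_zero"] = 0.0
        return super().fit(data)


def _pois_logpmf(y, mu):
    """Poisson log-pmf with exact handling of mu = 0 (point mass at 0)."""
    mu = np.asarray(mu, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = stats.poisson.logpmf(y, np.clip(mu, 1e-300, None))
    return np.where(mu == 0, np.where(y == 0, 0.0, -np.inf), out)


def fit_sv_rate(data: pd.DataFrame, response: str = "sv_count",
                random_effects: bool = True) -> BurdenFit:
    """Structural-variant rate per crypt per year of disease, with LRT.

    Returns a BurdenFit whose single coefficient row "rate" is in
    events/crypt/year; ``extras`` carries years_per_event and the duration
    LRT (statistic, df, p).
    """
    est = PoissonRateModel(response=response,
                           random_effects=random_effects).fit(data)
    stat, dof, p = est.lrt(data)
    coef = pd.DataFrame(
        {"estimate": [est.rate_], "se": [est.rate_se_],
         "lo": [est.rate_ci_[0]], "hi": [est.rate_ci_[1]]}, index=["rate"],
    )
    return BurdenFit(
        coef=coef,
        variance_components={"sd_patient_frailty": est.sigma_},
        loglik=est.loglik_, converged=est.converged_, n_obs=len(data),
        extras={"years_per_event": est.years_per_event_,
                "lrt": {"statistic": stat, "df": dof, "p": p}},
    )
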