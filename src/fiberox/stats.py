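"""Cohort-level statistics for per-specimen myofiber summaries.

Implements the analysis battery for a two-group (control vs PAD)
muscle-histology cohort:

* ANCOVA-style group comparison of specimen means with binary covariate
  adjustment (CAD, HTN) and least-squares adjusted means,
* percent differences under two denominators conventions,
* linear trend of damage on Fontaine stage (numeric 2/3/4),
* Pearson partial correlation of damage with ABI (residual method,
  Fisher-z confidence interval),
* within-patient repeated-measures model of quartile-class CSA means
  (class fixed effect, patient blocking effect) with least-squares
  post hoc contrasts of Q4 against Q1–Q3,
* inter-marker agreement (Pearson r of specimen means),
* demographics tests (chi-square for binary, one-way F for continuous).

All models are ordinary least squares on explicitly built design
matrices (statsmodels); p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

OUTCOME_COLUMNS = {
    "carbonyl": "mean_carbonyl_gsu",
    "hne": "mean_hne_gsu",
    "csa": "mean_csa_um2",
}


@dataclass
class GroupComparisonResult:
    outcome: str
    adjusted_mean_control: float
    adjusted_mean_pad: float
    F_stat: float  # partial F for the group term (= t² of the group coefficient)
    model_F: float  # overall model F, the F_{df_model, df_resid} convention
    df_model: int
    df_resid: int
    p_value: float  # p of the group term
    percent_difference: float  # vs_larger convention
    percent_difference_vs_control: float
    covariates: list[str] = field(default_factory=list)


@dataclass
class TrendResult:
    outcome: str
    slope: float
    slope_se: float
    r_squared: float
    p_value: float
    covariates: list[str] = field(default_factory=list)


@dataclass
class PartialCorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    covariates: list[str] = field(default_factory=list)


@dataclass
class QuartileModelResult:
    marker: str
    overall_F: float
    overall_p: float
    n_patients: int
    contrasts: list[dict] = field(default_factory=list)  # Q4 vs Q1/Q2/Q3


def _outcome_vector(summaries: pd.DataFrame, outcome: str) -> np.ndarray:
    try:
        col = OUTCOME_COLUMNS[outcome]
    except KeyError:
        raise ValueError(f"unknown outcome {outcome!r}") from None
    return summaries[col].to_numpy(dtype=float)


def _usable_covariates(summaries: pd.DataFrame, covariates) -> list[str]:
    usable = []
    for cov in covariates:
        vals = summaries[cov].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(f"covariate {cov!r} is constant; dropped", stacklevel=3)
            continue
        usable.append(cov)
    return usable


def percent_difference(mean_control: float, mean_pad: float,
                       convention: str = "vs_larger") -> float:
    """Signed percent difference of the PAD mean relative to control.

    ``vs_control``: (pad − control) / control × 100.
    ``vs_larger``: (pad − control) / max(control, pad) × 100 — the
    difference as a share of the larger mean, signed by direction.
    """
    if convention == "vs_control":
        denom = mean_control
    elif convention == "vs_larger":
        denom = max(mean_control, mean_pad)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if denom == 0:
        raise ZeroDivisionError("zero denominator in percent difference")
    return (mean_pad - mean_control) / denom * 100.0


def adjusted_group_comparison(summaries: pd.DataFrame, outcome: str,
                              covariates=("cad", "htn")) -> GroupComparisonResult:
    """ANCOVA-style control-vs-PAD comparison of a specimen-mean outcome.

    Fits ``outcome ~ group + covariates`` by OLS; the group effect is
    tested with a partial F (numerator df 1).  Adjusted means are the
    model predictions for each group with every covariate held at its
    pooled-sample prevalence (least-squares means).  A constant
    covariate is dropped with a warning rather than making the design
    singular.
    """
    groups = summaries["group"].astype(str)
    if set(groups) != {"control", "pad"}:
        raise ValueError("summaries must contain both 'control' and 'pad' groups")
    y = _outcome_vector(summaries, outcome)
    usable = _usable_covariates(summaries, covariates)
    g = (groups == "pad").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), g] +
                        [summaries[c].to_numpy(dtype=float) for c in usable])
    res = sm.OLS(y, X).fit()

    tval = res.tvalues[1]
    F_group = float(tval**2)
    p_group = float(res.pvalues[1])
    cov_means = [summaries[c].to_numpy(dtype=float).mean() for c in usable]
    x_control = np.array([1.0, 0.0, *cov_means])
    x_pad = np.array([1.0, 1.0, *cov_means])
    adj_control = float(x_control @ res.params)
    adj_pad = float(x_pad @ res.params)
    return GroupComparisonResult(
        outcome=outcome,
        adjusted_mean_control=adj_control,
        adjusted_mean_pad=adj_pad,
        F_stat=F_group,
        model_F=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p_value=p_group,
        percent_difference=percent_difference(adj_control, adj_pad, "vs_larger"),
        percent_difference_vs_control=percent_difference(adj_control, adj_pad,
                                                         "vs_control"),
        covariates=usable,
    )


def stage_trend(pad_summaries: pd.DataFrame, outcome: str,
                covariates=("cad", "htn")) -> TrendResult:
    """Linear regression of a PAD outcome on Fontaine stage (numeric 2/3/4).

    Reports the stage slope with its two-sided p-value and the fitted
    model's R².  Requires at least two distinct stages.
    """
    stage = pad_summaries["fontaine_stage"].to_numpy(dtype=float)
    if np.unique(stage).size < 2:
        raise ValueError("stage trend needs >= 2 distinct Fontaine stages")
    y = _outcome_vector(pad_summaries, outcome)
    usable = _usable_covariates(pad_summaries, covariates)
    X = np.column_stack([np.ones_like(y), stage] +
                        [pad_summaries[c].to_numpy(dtype=float) for c in usable])
    res = sm.OLS(y, X).fit()
    return TrendResult(
        outcome=outcome,
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        covariates=usable,
    )


def abi_partial_correlation(pad_summaries: pd.DataFrame, outcome: str,
                            covariates=("cad", "htn")) -> PartialCorrelationResult:
    """Pearson partial correlation of a PAD outcome with ABI.

    Residual method: the outcome and ABI are each regressed on the
    covariates, and the residuals are correlated.  The p-value uses the
    t distribution with n − k − 2 df; the 95% CI uses the Fisher z
    transform with variance 1/(n − k − 3), k = number of covariates.
    """
    usable = _usable_covariates(pad_summaries, covariates)
    k = len(usable)
    n = len(pad_summaries)
    if n <= k + 3:
        raise ValueError(f"partial correlation needs n > covariates + 3 (n={n}, k={k})")
    y = _outcome_vector(pad_summaries, outcome)
    abi = pad_summaries["abi"].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(n)] +
                        [pad_summaries[c].to_numpy(dtype=float) for c in usable])
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    ra = abi - Z @ np.linalg.lstsq(Z, abi, rcond=None)[0]
    r = float(np.corrcoef(ry, ra)[0, 1])

    df = n - k - 2
    r_clip = min(max(r, -0.999999999), 0.999999999)
    tstat = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2 * sps.t.sf(abs(tstat), df))
    z = np.arctanh(r_clip)
    half = sps.norm.ppf(0.975) / np.sqrt(n - k - 3)
    ci_low, ci_high = np.tanh(z - half), np.tanh(z + half)
    return PartialCorrelationResult(r=r, ci_low=float(ci_low), ci_high=float(ci_high),
                                    p_value=p, n=n, covariates=usable)


def quartile_repeated_measures(quartile_table: pd.DataFrame, marker: str,
                               alpha: float = 0.05,
                               holm: bool = False) -> QuartileModelResult:
    """Within-patient model of quartile-class CSA means.

    Class means (Q1–Q4 per patient) are modeled as class fixed effect +
    patient blocking effect; missing (empty) classes are dropped.  The
    overall class effect is a partial F-test; when significant at
    ``alpha``, least-squares contrasts of Q4 against Q1, Q2 and Q3 are
    reported (unadjusted p-values by default, Holm-adjusted on request).
    """
    sub = quartile_table[(quartile_table["marker"] == marker)
                         & quartile_table["mean_csa_um2"].notna()].copy()
    counts = sub.groupby("patient_id")["cls"].nunique()
    keep = counts[counts >= 2].index
    sub = sub[sub["patient_id"].isin(keep)]
    if sub["patient_id"].nunique() < 2:
        raise ValueError("repeated-measures model needs >= 2 patients "
                         "with >= 2 non-missing classes")

    y = sub["mean_csa_um2"].to_numpy(dtype=float)
    cls_d = pd.get_dummies(pd.Categorical(sub["cls"],
                                          categories=["Q1", "Q2", "Q3", "Q4"]),
                           drop_first=True, dtype=float)
    pat_d = pd.get_dummies(sub["patient_id"].astype(str), drop_first=True,
                           dtype=float)
    X = np.column_stack([np.ones_like(y), cls_d.to_numpy(), pat_d.to_numpy()])
    res = sm.OLS(y, X).fit()

    n_cls = cls_d.shape[1]
    R = np.zeros((n_cls, X.shape[1]))
    R[np.arange(n_cls), 1 + np.arange(n_cls)] = 1.0
    if res.ssr <= 1e-10 * max(res.centered_tss, 1.0):
        # saturated / zero-residual fit: no evidence either way
        class_effect = float(np.abs(res.params[1:1 + n_cls]).max())
        overall_F, overall_p = (np.inf, 0.0) if class_effect > 1e-10 else (0.0, 1.0)
    else:
        ftest = res.f_test(R)
        overall_F, overall_p = float(ftest.fvalue), float(ftest.pvalue)

    contrasts: list[dict] = []
    if overall_p < alpha:
        names = list(cls_d.columns)  # Q2, Q3, Q4
        q4 = names.index("Q4")
        raw = []
        for other in ("Q1", "Q2", "Q3"):
            c = np.zeros(X.shape[1])
            c[1 + q4] = 1.0
            if other != "Q1":
                c[1 + names.index(other)] = -1.0
            tt = res.t_test(c)
            raw.append({"pair": f"Q4-{other}",
                        "estimate": float(np.squeeze(tt.effect)),
                        "p": float(np.squeeze(tt.pvalue))})
        if holm:
            order = np.argsort([c["p"] for c in raw])
            m = len(raw)
            running = 0.0
            for rank, idx in enumerate(order):
                adj = min((m - rank) * raw[idx]["p"], 1.0)
                running = max(running, adj)
                raw[idx]["p_holm"] = running
        contrasts = raw
    return QuartileModelResult(marker=marker, overall_F=overall_F,
                               overall_p=overall_p,
                               n_patients=int(sub["patient_id"].nunique()),
                               contrasts=contrasts)


def marker_agreement(summaries: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of specimen mean carbonyl with mean HNE signal."""
    if len(summaries) < 3:
        raise ValueError("marker agreement needs >= 3 specimens")
    r, p = sps.pearsonr(summaries["mean_carbonyl_gsu"], summaries["mean_hne_gsu"])
    return float(r), float(p)


def demographics_table(metadata: pd.DataFrame,
                       binary=("cad", "htn"),
                       continuous=("abi",),
                       alpha: float = 0.05) -> pd.DataFrame:
    """Group-comparison tests for baseline variables.

    Binary variables: chi-square on the 2×2 table, without continuity
    correction.  Continuous variables: one-way linear-model F test.
    Variables significant at ``alpha`` are flagged as covariate
    candidates.  Tables with an empty row/column are reported as not
    computable (NaN statistic).
    """
    rows = []
    grp = metadata["group"].astype(str)
    for var in binary:
        table = pd.crosstab(grp, metadata[var])
        if table.shape != (2, 2) or (table.to_numpy() == 0).any() \
                or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            rows.append({"variable": var, "test": "chi_square",
                         "statistic": np.nan, "p_value": np.nan,
                         "covariate_candidate": False,
                         "note": "not computable (degenerate table)"})
            continue
        chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"variable": var, "test": "chi_square",
                     "statistic": float(chi2), "p_value": float(p),
                     "covariate_candidate": bool(p < alpha), "note": ""})
    for var in continuous:
        samples = [metadata.loc[grp == g, var].dropna().to_numpy(dtype=float)
                   for g in ("control", "pad")]
        if any(len(s) < 2 for s in samples):
            rows.append({"variable": var, "test": "linear_model_F",
                         "statistic": np.nan, "p_value": np.nan,
                         "covariate_candidate": False,
                         "note": "not computable (too few observations)"})
            continue
        f, p = sps.f_oneway(*samples)
        rows.append({"variable": var, "test": "linear_model_F",
                     "statistic": float(f), "p_value": float(p),
                     "covariate_candidate": bool(p < alpha), "note": ""})
    return pd.DataFrame(rows)


def chi_square_from_counts(yes_control: int, n_control: int,
                           yes_pad: int, n_pad: int) -> tuple[float, float]:
    """Chi-square (no continuity correction) for a 2×2 prevalence table."""
    table = np.array([[yes_control, n_control - yes_control],
                      [yes_pad, n_pad - yes_pad]])
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def run_cohort_statistics(summaries: pd.DataFrame, quartile_table: pd.DataFrame,
                          covariates=("cad", "htn")) -> dict:
    """Run the full analysis battery; infeasible analyses record an error.

    Returns a JSON-serializable dict, one entry per analysis.
    """
    out: dict = {"covariates": list(covariates)}
    pad = summaries[summaries["group"] == "pad"]

    out["group_comparison"] = {}
    for outcome in ("carbonyl", "hne", "csa"):
        out["group_comparison"][outcome] = _maybe(
            lambda o=outcome: vars(adjusted_group_comparison(summaries, o, covariates)))
    out["stage_trend"] = {}
    out["abi_partial_correlation"] = {}
    for outcome in ("carbonyl", "hne"):
        out["stage_trend"][outcome] = _maybe(
            lambda o=outcome: vars(stage_trend(pad, o, covariates)))
        out["abi_partial_correlation"][outcome] = _maybe(
            lambda o=outcome: vars(abi_partial_correlation(pad, o, covariates)))
    out["quartile_repeated_measures"] = {}
    pad_ids = set(pad["patient_id"])
    ctl_ids = set(summaries.loc[summaries["group"] == "control", "patient_id"])
    for marker in ("carbonyl", "hne"):
        for group, ids in (("pad", pad_ids), ("control", ctl_ids)):
            qsub = quartile_table[quartile_table["patient_id"].isin(ids)]
            out["quartile_repeated_measures"][f"{marker}_{group}"] = _maybe(
                lambda q=qsub, m=marker: vars(quartile_repeated_measures(q, m)))
    out["marker_agreement_pad"] = _maybe(
        lambda: dict(zip(("r", "p_value"), marker_agreement(pad))))
    out["demographics"] = _maybe(
        lambda: demographics_table(summaries).to_dict(orient="records"))
    return out


def _maybe(fn):
    try:
        return fn()
    except (ValueError, ZeroDivisionError) as exc:
        return {"error": str(exc)}
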