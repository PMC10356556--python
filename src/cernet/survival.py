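"""Signature scoring, median-split risk groups, cumulative hazard, and Cox
regression.

Samples are scored by the mean of per-gene z-scores over a gene signature;
the cohort is split at the median score (ties go to the low-risk group) and
the groups are compared by the Nelson-Aalen cumulative hazard and the
log-rank test. Hazard ratios come from a Cox proportional-hazards fit with
Efron tie handling (via lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .datatypes import ExpressionDataset, SurvivalTable, normalize_symbol

__all__ = [
    "SignatureScores",
    "HazardEstimate",
    "signature_zscore",
    "stratify_median",
    "nelson_aalen",
    "km_cumhaz",
    "cox_fit",
]


@dataclass
class SignatureScores:
    """Per-sample signature z-scores: ``scores`` indexed by sample ID."""

    scores: pd.Series
    n_genes_used: int
    missing_genes: list[str]


@dataclass(frozen=True)
class HazardEstimate:
    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    model: str  # univariable | multivariable

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError(
                f"inconsistent CI for {self.variable}: "
                f"[{self.ci_low}, {self.ci_high}] vs HR {self.hr}"
            )


def signature_zscore(dataset: ExpressionDataset, signature: list[str],
                     signature_name: str = "signature") -> SignatureScores:
    """Mean of per-gene z-scores over the signature genes present.

    Each gene is standardized across samples with the population (1/n)
    standard deviation; zero-variance genes are excluded with a warning.
    """
    if len(dataset.samples) < 3:
        raise ValueError("need >= 3 samples to z-score")
    wanted = [normalize_symbol(g) for g in signature]
    present = [g for g in wanted if g in dataset.values.index]
    missing = [g for g in wanted if g not in dataset.values.index]
    if not present:
        raise KeyError(f"no gene of signature {signature_name!r} present in the dataset")
    sub = dataset.values.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"excluding zero-variance signature genes: {sorted(sub.index[flat])}"
        )
        sub = sub.loc[~flat]
        sd = sd[~flat]
    if sub.empty:
        raise ValueError(f"all present genes of {signature_name!r} have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return SignatureScores(
        scores=z.mean(axis=0), n_genes_used=len(sub), missing_genes=missing
    )


def stratify_median(scores: pd.Series) -> pd.Series:
    """'high' iff score strictly above the median; ties at the median go low."""
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to stratify")
    med = float(scores.median())
    groups = pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="group"
    )
    if groups.nunique() < 2:
        raise ValueError("cannot stratify: all scores identical")
    return groups


def nelson_aalen(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Nelson-Aalen cumulative hazard: increments d_j/n_j at each event time.

    Returns a frame with columns time, d (events), n (at risk), increment,
    cumhaz; one row per distinct event time, events only.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    cum = 0.0
    n_total = len(times)
    for t in np.unique(times[events == 1]):
        d = int(((times == t) & (events == 1)).sum())
        n_at_risk = int((times >= t).sum())
        inc = d / n_at_risk
        cum += inc
        rows.append({"time": float(t), "d": d, "n": n_at_risk,
                     "increment": inc, "cumhaz": cum})
    return pd.DataFrame(rows, columns=["time", "d", "n", "increment", "cumhaz"])


def km_cumhaz(groups: pd.Series, survival: SurvivalTable) -> dict:
    """Per-group Nelson-Aalen cumulative hazard plus the log-rank comparison.

    Only samples present in both the scores and the survival table enter;
    the number dropped on either side is reported under ``n_unmatched``.
    """
    common = groups.index.intersection(survival.data.index)
    n_unmatched = (len(groups) - len(common)) + (len(survival) - len(common))
    if len(common) == 0:
        raise ValueError("no overlap between scored samples and survival table")
    g = groups.loc[common]
    surv = survival.data.loc[common]
    curves = {
        label: nelson_aalen(
            surv.loc[g == label, "time"].to_numpy(),
            surv.loc[g == label, "event"].to_numpy(),
        )
        for label in sorted(g.unique())
    }
    out = {"curves": curves, "n_unmatched": int(n_unmatched),
           "logrank_stat": np.nan, "logrank_p": np.nan}
    if surv["event"].sum() == 0:
        raise ValueError("no events in any group: log-rank undefined")
    labels = sorted(g.unique())
    if len(labels) == 2:
        m0, m1 = (g == labels[0]), (g == labels[1])
        res = logrank_test(
            surv.loc[m0, "time"], surv.loc[m1, "time"],
            event_observed_A=surv.loc[m0, "event"],
            event_observed_B=surv.loc[m1, "event"],
        )
        out["logrank_stat"], out["logrank_p"] = float(res.test_statistic), float(res.p_value)
    elif len(labels) > 2:
        res = multivariate_logrank_test(surv["time"], g, surv["event"])
        out["logrank_stat"], out["logrank_p"] = float(res.test_statistic), float(res.p_value)
    return out


def cox_fit(
    survival: SurvivalTable,
    predictors: pd.DataFrame,
    mode: str = "univariable",
) -> list[HazardEstimate]:
    """Cox proportional-hazards regression (Efron ties) on sample-level predictors.

    ``univariable`` fits each predictor column alone; ``multivariable`` fits
    them jointly. Returns HR = exp(beta), Wald 95% CI and p per predictor.
    """
    if mode not in ("univariable", "multivariable"):
        raise ValueError(f"unknown mode {mode!r}")
    common = predictors.index.intersection(survival.data.index)
    if len(common) == 0:
        raise ValueError("no overlap between predictors and survival table")
    surv = survival.data.loc[common, ["time", "event"]]
    preds = predictors.loc[common]
    for col in preds.columns:
        if preds[col].nunique() <= 1:
            raise ValueError(f"constant predictor {col!r}: Cox fit undefined")
    if int(surv["event"].sum()) < 10:
        warnings.warn(
            f"only {int(surv['event'].sum())} events; hazard estimates unstable"
        )

    def _fit(cols: list[str], model: str) -> list[HazardEstimate]:
        df = pd.concat([surv, preds[cols]], axis=1)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # lifelines raises ConvergenceError and warnings
            raise RuntimeError(f"Cox fit failed for {cols}: {exc}") from exc
        summ = cph.summary
        return [
            HazardEstimate(
                variable=str(var),
                hr=float(summ.loc[var, "exp(coef)"]),
                ci_low=float(summ.loc[var, "exp(coef) lower 95%"]),
                ci_high=float(summ.loc[var, "exp(coef) upper 95%"]),
                p=float(summ.loc[var, "p"]),
                model=model,
            )
            for var in summ.index
        ]

    if mode == "univariable":
        out: list[HazardEstimate] = []
        for col in preds.columns:
            out.extend(_fit([col], "univariable"))
        return out
    return _fit(list(preds.columns), "multivariable")
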