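"""Downstream association analyses for per-sample signature scores.

Covers the outcome analyses a histology score feeds into: survival
stratification (log-rank on a median or zero split), univariate and
multivariate Cox proportional-hazards regression, binary genomic-feature
association (Wilcoxon rank-sum with a minimum-recurrence filter),
drug-sensitivity rank correlation, and responder classification
(ROC/AUC plus a rank-sum comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "dichotomize",
    "logrank_test",
    "cox_regression",
    "feature_association",
    "rank_correlation",
    "response_classification",
    "ROCResult",
]


def _aligned(scores: pd.Series, other: pd.DataFrame | pd.Series):
    scores = pd.Series(scores)
    common = scores.index.intersection(other.index if other.ndim == 1 else other.index)
    return scores.loc[common], other.loc[common]


def dichotomize(scores: pd.Series, method: str = "median") -> pd.Series:
    """Split samples into high/low groups at the median or at zero.

    Values exactly at the cutoff go to the low group.  Returns a boolean
    Series (True = high).
    """
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    if method == "median":
        cutoff = float(scores.median())
        if scores.nunique() == 1:
            raise ValueError("all scores identical; median split undefined")
    elif method == "zero":
        cutoff = 0.0
    else:
        raise ValueError(f"unknown dichotomization method {method!r}")
    out = scores > cutoff
    out.name = "high"
    return out


def logrank_test(groups: pd.Series, survival: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    ``groups`` is a boolean/binary Series aligned to ``survival``, which
    must carry ``time`` (months) and ``event`` (1 = observed) columns.
    """
    groups, survival = _aligned(pd.Series(groups), survival)
    g = groups.astype(bool)
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    if survival["event"].sum() < 1:
        raise ValueError("no events observed")
    res = _ll_logrank(
        survival.loc[g, "time"],
        survival.loc[~g, "time"],
        event_observed_A=survival.loc[g, "event"],
        event_observed_B=survival.loc[~g, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_regression(
    scores: pd.Series,
    survival: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    score_name: str = "score",
) -> pd.DataFrame:
    """Cox proportional-hazards fit of survival on a score (+ covariates).

    The score may be continuous (e.g. the L-score itself, or a
    standardized version for a per-SD hazard ratio) or a binary group
    indicator.  Covariates, when given, are joined by sample id (the
    multivariate model; e.g. age, sex, binary stage).

    Returns
    -------
    DataFrame indexed by covariate with columns ``coef``, ``hr``,
    ``ci_lower``, ``ci_upper``, ``p`` (Wald).
    """
    scores = pd.Series(scores, name=score_name).astype(float)
    df = survival[["time", "event"]].join(scores, how="inner")
    if covariates is not None:
        df = df.join(covariates.astype(float), how="inner")
    if df["event"].sum() < 1:
        raise ValueError("no events observed")
    n_cov = df.shape[1] - 2
    if df["event"].sum() < 10 * n_cov:
        warnings.warn(
            f"only {int(df['event'].sum())} events for {n_cov} covariates; "
            "estimates may be unstable"
        )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    out.index.name = "covariate"
    return out


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum via Mann-Whitney U.

    Exact enumeration when the smaller group has <= 10 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction.
    """
    pooled = np.concatenate([x, y])
    exact = min(len(x), len(y)) <= 10 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class ROCResult:
    """ROC curve, AUC and rank-sum p for a binary response comparison."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    p_wilcoxon: float
    n_pos: int
    n_neg: int


def feature_association(
    scores: pd.Series,
    features: pd.DataFrame,
    min_count: int = 20,
    alpha: float = 0.01,
    *,
    adjust: bool = False,
) -> pd.DataFrame:
    """Associate binary genomic features with per-sample scores.

    Features (rows of ``features``, samples in columns, entries 0/1 for
    e.g. mutation, amplification or deletion status) altered in fewer
    than ``min_count`` samples are excluded before testing.  For each
    remaining feature the scores of altered vs wild-type samples are
    compared with the two-sided Wilcoxon rank-sum test; features with
    unadjusted p < ``alpha`` are flagged significant (``adjust=True``
    switches the flag to BH-adjusted p).

    Returns
    -------
    DataFrame indexed by feature with columns ``n_altered``,
    ``n_wildtype``, ``statistic``, ``p``, ``direction`` (sign of the
    altered - wild-type median score difference) and ``significant``.
    """
    scores = pd.Series(scores).astype(float)
    feats = features.loc[:, features.columns.intersection(scores.index)]
    if feats.shape[1] < 2:
        raise ValueError("features and scores share fewer than 2 samples")
    vals = feats.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("feature matrix must be binary 0/1")
    s = scores.loc[feats.columns].to_numpy()

    n_alt = vals.sum(axis=1).astype(int)
    n_wt = vals.shape[1] - n_alt
    keep = (n_alt >= min_count) & (n_wt >= 1)
    if not keep.any():
        raise ValueError(f"no feature altered in at least {min_count} samples")

    rows = []
    for i in np.flatnonzero(keep):
        alt = s[vals[i] == 1]
        wt = s[vals[i] == 0]
        stat, p = _rank_sum(alt, wt)
        direction = int(np.sign(np.median(alt) - np.median(wt)))
        rows.append((feats.index[i], int(n_alt[i]), int(n_wt[i]), stat, p, direction))
    out = pd.DataFrame(
        rows, columns=["feature_id", "n_altered", "n_wildtype", "statistic", "p", "direction"]
    ).set_index("feature_id")
    if adjust:
        from .signature import benjamini_hochberg

        out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["fdr"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def rank_correlation(scores: pd.Series, y: pd.Series) -> tuple[float, float]:
    """Spearman correlation between scores and a per-sample scalar.

    Typical use: drug sensitivity as -ln(IC50 + 1) or -AUC, where higher
    values mean higher sensitivity.  Pairs with missing ``y`` are
    dropped; at least 5 complete pairs are required.
    """
    scores = pd.Series(scores).astype(float)
    y = pd.Series(y).astype(float)
    df = pd.concat([scores.rename("s"), y.rename("y")], axis=1, join="inner").dropna()
    if len(df) < 5:
        raise ValueError("need at least 5 paired observations")
    rho, p = stats.spearmanr(df["s"], df["y"])
    return float(rho), float(p)


def response_classification(scores: pd.Series, labels: pd.Series) -> ROCResult:
    """ROC curve / AUC of a score for a binary responder label.

    AUC is the probability that a randomly chosen responder outscores a
    randomly chosen non-responder, ties counting one half (equivalently
    U / (n1 * n2)).  Also reports the two-sided Wilcoxon rank-sum p for
    the responder vs non-responder score comparison.
    """
    scores = pd.Series(scores).astype(float)
    labels = pd.Series(labels)
    df = pd.concat([scores.rename("s"), labels.rename("y")], axis=1, join="inner").dropna()
    y = df["y"].astype(int).to_numpy()
    s = df["s"].to_numpy()
    if y.min() == y.max():
        raise ValueError("both responder classes must be present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    _, p = _rank_sum(s[y == 1], s[y == 0])
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        p_wilcoxon=p,
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
    )
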