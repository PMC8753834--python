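"""Subtype-specific differential profiles and weighted gene signatures.

A histological subtype (e.g. lepidic or solid growth pattern of lung
adenocarcinoma) is characterized by comparing the expression of every gene
in samples of that subtype against all remaining samples with a two-sample
t-test.  The resulting per-gene (t, p) pairs are converted into a pair of
weight vectors ``w_plus`` / ``w_minus`` in [0, 1]: up-regulated genes
(t > 0) receive ``min(-log p, cap) / cap`` in ``w_plus``, down-regulated
genes the analogous value in ``w_minus``.  The pair is the *weighted
signature* consumed by :mod:`histosig.scoring`.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WeightedSignature",
    "differential_expression",
    "benjamini_hochberg",
    "build_weighted_signature",
    "select_top_subtype_genes",
    "SubtypeSignatureBuilder",
]


@dataclass(frozen=True)
class WeightedSignature:
    """Paired per-gene weight vectors for one histological subtype.

    Parameters
    ----------
    weights :
        DataFrame indexed by gene id with columns ``w_plus`` and
        ``w_minus``, both in [0, 1].  For every gene at most one of the
        two weights is non-zero (a gene is either up- or down-regulated
        in the target subtype, never both).
    trim_cap :
        The trimming cap applied to ``-log p`` before rescaling.
    target_subtype :
        Optional label of the subtype the signature characterizes.
    """

    weights: pd.DataFrame
    trim_cap: float = 10.0
    target_subtype: str | None = None

    def __post_init__(self) -> None:
        w = self.weights
        if not isinstance(w, pd.DataFrame) or set(w.columns) < {"w_plus", "w_minus"}:
            raise ValueError("weights must be a DataFrame with w_plus/w_minus columns")
        if w.index.has_duplicates:
            raise ValueError("duplicate gene ids in signature")
        wp = w["w_plus"].to_numpy(float)
        wm = w["w_minus"].to_numpy(float)
        if np.isnan(wp).any() or np.isnan(wm).any():
            raise ValueError("signature weights contain missing values")
        if (wp < 0).any() or (wp > 1).any() or (wm < 0).any() or (wm > 1).any():
            raise ValueError("signature weights must lie in [0, 1]")
        if (np.minimum(wp, wm) > 0).any():
            raise ValueError("a gene cannot carry both w_plus > 0 and w_minus > 0")
        if not ((wp > 0).any() or (wm > 0).any()):
            raise ValueError("signature has no informative gene (all weights zero)")
        if not self.trim_cap > 0:
            raise ValueError("trim_cap must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.weights.index

    @property
    def w_plus(self) -> pd.Series:
        return self.weights["w_plus"]

    @property
    def w_minus(self) -> pd.Series:
        return self.weights["w_minus"]

    def swapped(self) -> "WeightedSignature":
        """Return the signature with ``w_plus`` and ``w_minus`` exchanged."""
        w = self.weights.rename(columns={"w_plus": "w_minus", "w_minus": "w_plus"})
        return WeightedSignature(w[["w_plus", "w_minus"]], self.trim_cap, self.target_subtype)

    def __len__(self) -> int:
        return len(self.weights)


def _align_annotation(x: pd.DataFrame, annotations: pd.Series) -> pd.Series:
    ann = pd.Series(annotations)
    missing = ann.index.difference(x.columns)
    if len(missing):
        raise ValueError(f"annotated samples absent from expression matrix: {list(missing)[:5]}")
    return ann


def differential_expression(
    x: pd.DataFrame,
    annotations: pd.Series,
    target: str,
    *,
    test: str = "student",
) -> pd.DataFrame:
    """One-vs-rest differential expression for a target subtype.

    Compares, gene by gene, the samples annotated as ``target`` against all
    other annotated samples with a two-sample t-test.  Positive t means
    higher expression in the target subtype.

    Parameters
    ----------
    x :
        Expression matrix, genes in rows, samples in columns.
    annotations :
        Series mapping sample id -> subtype label; every annotated sample
        must be a column of ``x``.
    target :
        The subtype whose samples form the foreground group.
    test :
        ``"student"`` for the pooled-variance two-sample t-test, ``"welch"``
        for unequal variances.

    Returns
    -------
    DataFrame indexed by gene with columns ``t``, ``p`` and ``fdr``
    (Benjamini-Hochberg across all genes).  Genes with zero variance in
    both groups are assigned t = 0, p = 1 so that the profile stays
    aligned with the matrix.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test flavor {test!r}")
    ann = _align_annotation(x, annotations)
    tgt_samples = ann.index[ann == target]
    rest_samples = ann.index[ann != target]
    if len(tgt_samples) == 0:
        raise ValueError(f"target subtype {target!r} absent from annotations")
    if len(tgt_samples) < 2 or len(rest_samples) < 2:
        raise ValueError("both groups need at least 2 samples")

    a = x.loc[:, tgt_samples].to_numpy(float)
    b = x.loc[:, rest_samples].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    t = np.asarray(t, float)
    p = np.asarray(p, float)

    # zero variance in both groups: no evidence either way
    degenerate = ~np.isfinite(t)
    both_const = degenerate & np.isnan(t)
    t[both_const] = 0.0
    p[both_const] = 1.0
    # constant within groups but different means: saturate instead of +-inf
    inf = np.isinf(t)
    if inf.any():
        t[inf] = np.sign(t[inf]) * 1e300
        p[inf] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame({"t": t, "p": p}, index=x.index)
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    out.attrs["target_subtype"] = target
    out.attrs["n_target"] = int(len(tgt_samples))
    out.attrs["n_rest"] = int(len(rest_samples))
    return out


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), clipped at 1."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_weighted_signature(
    profile: pd.DataFrame,
    trim_cap: float = 10.0,
    *,
    log_base: str = "e",
    rescale: str = "cap",
    target_subtype: str | None = None,
) -> WeightedSignature:
    """Convert a differential profile into a paired weighted signature.

    For gene k with statistic t_k and p-value p_k::

        w_plus_k  = min(-log p_k, trim_cap) / trim_cap   if t_k > 0 else 0
        w_minus_k = min(-log p_k, trim_cap) / trim_cap   if t_k < 0 else 0

    With natural log and the default cap of 10, a weight saturates at 1
    for p <= exp(-10) ~ 4.5e-5.

    Parameters
    ----------
    profile :
        DataFrame indexed by gene with columns ``t`` and ``p``.
    trim_cap :
        Cap applied to ``-log p`` before rescaling; positive.
    log_base :
        ``"e"`` (natural log, default) or ``"10"``.
    rescale :
        ``"cap"`` divides by ``trim_cap`` (default; weights are comparable
        across signatures), ``"minmax"`` divides by the maximum trimmed
        value so the largest weight is exactly 1.
    """
    if len(profile) == 0:
        raise ValueError("empty differential profile")
    if not trim_cap > 0:
        raise ValueError("trim_cap must be positive")
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    if rescale not in ("cap", "minmax"):
        raise ValueError("rescale must be 'cap' or 'minmax'")

    t = profile["t"].to_numpy(float)
    p = profile["p"].to_numpy(float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    neglog = -np.log(p) if log_base == "e" else -np.log10(p)
    trimmed = np.minimum(neglog, trim_cap)
    wp = np.where(t > 0, trimmed, 0.0)
    wm = np.where(t < 0, trimmed, 0.0)
    denom = trim_cap if rescale == "cap" else max(wp.max(), wm.max())
    if denom == 0 or not ((wp > 0).any() or (wm > 0).any()):
        raise ValueError("all weights are zero: no informative genes in profile")
    weights = pd.DataFrame(
        {"w_plus": wp / denom, "w_minus": wm / denom}, index=profile.index
    )
    if target_subtype is None:
        target_subtype = profile.attrs.get("target_subtype")
    return WeightedSignature(weights, trim_cap=float(trim_cap), target_subtype=target_subtype)


def _rank_profile(profile: pd.DataFrame) -> pd.Index:
    """Genes ordered by specificity: p ascending, |t| descending, id ascending."""
    order = np.lexsort(
        (
            profile.index.to_numpy(str),
            -np.abs(profile["t"].to_numpy(float)),
            profile["p"].to_numpy(float),
        )
    )
    return profile.index[order]


def select_top_subtype_genes(
    profiles: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
    k: int = 200,
) -> pd.Index:
    """Union of the k most subtype-specific genes across profiles.

    Within each profile genes are ranked by ascending p, ties broken by
    descending |t| then gene id; the per-profile top-k sets are merged
    (duplicates collapse).  With five subtype profiles and disjoint top
    sets at k = 200 this yields the 1000-gene panel used for clustering
    the histological subtypes.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    else:
        profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one differential profile required")
    if k < 1:
        raise ValueError("k must be >= 1")
    selected: set[str] = set()
    for prof in profiles:
        if k > len(prof):
            raise ValueError(f"k={k} exceeds gene count {len(prof)}")
        selected.update(_rank_profile(prof)[:k])
    return pd.Index(sorted(selected), name="gene")


class SubtypeSignatureBuilder(BaseEstimator):
    """Fit per-subtype differential profiles and weighted signatures.

    scikit-learn style estimator: ``fit(X, y)`` takes a samples x genes
    DataFrame ``X`` and per-sample subtype labels ``y`` and derives, for
    each requested subtype, a one-vs-rest differential profile and the
    corresponding :class:`WeightedSignature`.

    Parameters
    ----------
    subtypes : list of str, optional
        Subtypes to build signatures for; default all labels present in y.
    test : {"student", "welch"}
        t-test flavor for the one-vs-rest comparison.
    trim_cap : float
        Cap on -log p in the weight construction (default 10).
    log_base : {"e", "10"}
    rescale : {"cap", "minmax"}
    top_k : int or None
        If set, also compute the merged top-k most specific gene panel
        across subtypes (``top_genes_``).

    Attributes
    ----------
    classes_ : list of subtype labels fitted
    profiles_ : dict subtype -> DataFrame(t, p, fdr)
    signatures_ : dict subtype -> WeightedSignature
    top_genes_ : pd.Index (only when ``top_k`` is not None)
    """

    def __init__(
        self,
        subtypes: list[str] | None = None,
        *,
        test: str = "student",
        trim_cap: float = 10.0,
        log_base: str = "e",
        rescale: str = "cap",
        top_k: int | None = None,
    ):
        self.subtypes = subtypes
        self.test = test
        self.trim_cap = trim_cap
        self.log_base = log_base
        self.rescale = rescale
        self.top_k = top_k

    def fit(self, X: pd.DataFrame, y) -> "SubtypeSignatureBuilder":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame with gene ids as columns")
        y = pd.Series(np.asarray(y), index=X.index)
        x = X.T  # genes x samples, the orientation the field's tables use
        labels = self.subtypes if self.subtypes is not None else sorted(pd.unique(y))
        self.classes_ = list(labels)
        self.profiles_ = {}
        self.signatures_ = {}
        for label in self.classes_:
            prof = differential_expression(x, y, label, test=self.test)
            self.profiles_[label] = prof
            try:
                self.signatures_[label] = build_weighted_signature(
                    prof,
                    self.trim_cap,
                    log_base=self.log_base,
                    rescale=self.rescale,
                    target_subtype=label,
                )
            except ValueError as err:
                warnings.warn(f"no signature for subtype {label!r}: {err}")
        if self.top_k is not None:
            self.top_genes_ = select_top_subtype_genes(self.profiles_, self.top_k)
        self.n_features_in_ = X.shape[1]
        return self

    def get_signature(self, subtype: str) -> WeightedSignature:
        return self.signatures_[subtype]
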