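"""Rank-based single-sample enrichment scoring with a permutation null.

Given one sample's expression profile and a weighted signature
(w_plus, w_minus), genes are sorted by decreasing expression into
e = (e1, ..., en) and the skew of signature mass toward the top of the
ranking is measured by comparing a foreground with a background
cumulative curve::

    f(i) = sum_{k<=i} |e_k w_k| / sum_k |e_k w_k|
    b(i) = sum_{k<=i} |e_k (1 - w_k)| / sum_k |e_k (1 - w_k)|

The raw enrichment score is the signed deviation f - b at the index of
maximum absolute deviation (the weighted Kolmogorov-Smirnov convention of
GSEA-style statistics).  It is normalized into a z-score against a null
distribution obtained by randomly permuting the gene-to-weight assignment
with e held fixed.  A sample's final score is S = S+ - S-, with both
components normalized against the *same* permutation index sequence so
the difference is not dominated by independent Monte-Carlo noise and
exchanging w+ and w- negates S exactly.

Higher L-scores (lepidic signature) or S-scores (solid signature)
indicate a higher relative abundance of that histological component in
the sample.
"""

from __future__ import annotations

import warnings
import zlib
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .signature import WeightedSignature

__all__ = [
    "RankedExpression",
    "RunningEnrichment",
    "ScoreResult",
    "rank_genes",
    "running_enrichment",
    "permutation_normalize",
    "score_sample",
    "score_cohort",
    "infiltration_scores",
    "EnrichmentScorer",
]

# permutation ES matrices are evaluated in chunks of at most this many cells
_CHUNK_CELLS = 2_500_000


@dataclass(frozen=True)
class RankedExpression:
    """A sample's genes sorted by decreasing expression.

    Ties are broken lexicographically by gene id, so the ranking is
    deterministic and platform-independent.  Negative values (two-channel
    log ratios) are ranked signed; the enrichment curves then use |e|.
    """

    gene_ids: np.ndarray
    e: np.ndarray

    def __len__(self) -> int:
        return self.e.size


@dataclass(frozen=True)
class RunningEnrichment:
    """Foreground/background cumulative curves and their maximum deviation."""

    f: np.ndarray
    b: np.ndarray
    i_star: int  # 0-based index of maximum |f - b|, smallest index on ties
    es_raw: float  # signed deviation f[i_star] - b[i_star], in [-1, 1]


@dataclass(frozen=True)
class ScoreResult:
    """Normalized component scores and final score for one sample."""

    s_plus: float
    s_minus: float
    score: float
    n_perm: int
    seed: int
    overlap_fraction: float
    es_plus_raw: float
    es_minus_raw: float
    degenerate: bool = False


def rank_genes(expr: pd.Series) -> RankedExpression:
    """Sort a sample's expression vector into decreasing order."""
    if len(expr) < 2:
        raise ValueError("need at least 2 genes to rank")
    vals = expr.to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("expression vector contains missing values")
    ids = expr.index.to_numpy(str)
    order = np.lexsort((ids, -vals))  # primary: value desc; ties: id asc
    return RankedExpression(gene_ids=ids[order], e=vals[order])


def _curves(a: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fg = a * w
    bg = a * (1.0 - w)
    fg_total = fg.sum()
    bg_total = bg.sum()
    if fg_total <= 0:
        raise ValueError("degenerate weights: foreground mass is zero")
    if bg_total <= 0:
        raise ValueError("degenerate weights: background mass is zero")
    return np.cumsum(fg) / fg_total, np.cumsum(bg) / bg_total


def running_enrichment(ranked: RankedExpression, w) -> RunningEnrichment:
    """Foreground/background curves and raw enrichment score for one sample.

    Parameters
    ----------
    ranked :
        The sample's ranked expression.
    w :
        Weight vector aligned to ``ranked.gene_ids``, values in [0, 1].
    """
    w = np.asarray(w, float)
    if w.shape != ranked.e.shape:
        raise ValueError("weight vector not aligned to ranked expression")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    f, b = _curves(np.abs(ranked.e), w)
    d = f - b
    i_star = int(np.argmax(np.abs(d)))  # argmax takes the smallest index on ties
    return RunningEnrichment(f=f, b=b, i_star=i_star, es_raw=float(d[i_star]))


def _es_batch(a: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Raw ES for each row of a weight matrix W (m, n); a = |e|.

    Rows whose foreground or background mass vanishes get ES 0.
    """
    fg = a[None, :] * W
    bg = a[None, :] * (1.0 - W)
    fs = fg.sum(axis=1)
    bs = bg.sum(axis=1)
    ok = (fs > 0) & (bs > 0)
    fs[~ok] = 1.0
    bs[~ok] = 1.0
    d = np.cumsum(fg, axis=1) / fs[:, None] - np.cumsum(bg, axis=1) / bs[:, None]
    idx = np.argmax(np.abs(d), axis=1)
    es = d[np.arange(d.shape[0]), idx]
    es[~ok] = 0.0
    return es


def _null_es(
    a: np.ndarray,
    weight_vectors: list[np.ndarray],
    rng: np.random.Generator,
    n_perm: int,
) -> list[np.ndarray]:
    """Null ES for each weight vector under shared random permutations.

    The same permutation index sequence is applied to every vector in
    ``weight_vectors`` (the shared-permutation contract behind the exact
    antisymmetry of S = S+ - S-).
    """
    n = a.size
    chunk = max(1, _CHUNK_CELLS // max(n, 1))
    nulls = [np.empty(n_perm) for _ in weight_vectors]
    done = 0
    base = np.arange(n)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = rng.permuted(np.broadcast_to(base, (m, n)), axis=1)
        for out, w in zip(nulls, weight_vectors):
            out[done : done + m] = _es_batch(a, w[idx])
        done += m
    return nulls


def _normalize(es_raw: float, null: np.ndarray) -> tuple[float, bool]:
    mu = null.mean()
    sd = null.std(ddof=1)
    # ES lives on [-1, 1]; a null spread at float-rounding scale (e.g.
    # constant weights, where f and b cancel) is degeneracy, not signal
    if sd <= 1e-12:
        return 0.0, True
    return float((es_raw - mu) / sd), False


def permutation_normalize(
    es_raw: float,
    ranked: RankedExpression,
    w,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    return_null: bool = False,
):
    """z-normalize a raw enrichment score against its permutation null.

    The null is formed by recomputing the raw ES after uniformly random
    permutations of the gene-to-weight assignment, with the ranked
    expression held fixed.  Returns ``(es_raw - mean_null) / sd_null``;
    a null with zero spread is degenerate and maps to 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    w = np.asarray(w, float)
    rng = np.random.default_rng(seed)
    (null,) = _null_es(np.abs(ranked.e), [w], rng, n_perm)
    z, degenerate = _normalize(es_raw, null)
    if degenerate:
        warnings.warn("degenerate permutation null (zero spread); score set to 0")
    if return_null:
        return z, null
    return z


def score_sample(
    expr: pd.Series,
    sig: WeightedSignature,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    min_overlap: float = 0.5,
    warn_overlap: float = 0.8,
) -> ScoreResult:
    """Score one sample against a weighted signature.

    The sample's genes are intersected with the signature's; both the
    w_plus and w_minus components are scored against the same permutation
    index sequence and the final score is S = S+ - S-.

    Raises
    ------
    ValueError
        If fewer than ``min_overlap`` of the signature genes are present
        in the sample, or the signature is degenerate on the overlap.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    common = expr.index.intersection(sig.genes)
    overlap = len(common) / len(sig.genes)
    if overlap < min_overlap:
        raise ValueError(
            f"only {overlap:.0%} of signature genes present in sample "
            f"(threshold {min_overlap:.0%})"
        )
    if overlap < warn_overlap:
        warnings.warn(f"signature overlap is low ({overlap:.0%})")

    ranked = rank_genes(expr.loc[common])
    w = sig.weights.loc[ranked.gene_ids]
    wp = w["w_plus"].to_numpy(float)
    wm = w["w_minus"].to_numpy(float)
    # a one-sided profile (e.g. marker-gene w_plus only) has a silent
    # component: its score is 0 rather than an error
    active_p = wp.sum() > 0 and (1 - wp).sum() > 0
    active_m = wm.sum() > 0 and (1 - wm).sum() > 0
    if not (active_p or active_m):
        raise ValueError("degenerate signature on the sample overlap")

    es_p = running_enrichment(ranked, wp).es_raw if active_p else 0.0
    es_m = running_enrichment(ranked, wm).es_raw if active_m else 0.0

    rng = np.random.default_rng(seed)
    null_p, null_m = _null_es(np.abs(ranked.e), [wp, wm], rng, n_perm)
    s_plus, deg_p = _normalize(es_p, null_p) if active_p else (0.0, True)
    s_minus, deg_m = _normalize(es_m, null_m) if active_m else (0.0, True)
    return ScoreResult(
        s_plus=s_plus,
        s_minus=s_minus,
        score=s_plus - s_minus,
        n_perm=n_perm,
        seed=seed,
        overlap_fraction=overlap,
        es_plus_raw=es_p,
        es_minus_raw=es_m,
        degenerate=deg_p or deg_m,
    )


def sample_seed(base_seed: int, sample_id: str) -> int:
    """Deterministic per-sample seed, invariant to sample order."""
    return (int(base_seed) + zlib.crc32(str(sample_id).encode())) % (2**31)


def score_cohort(
    x: pd.DataFrame,
    sig: WeightedSignature,
    n_perm: int = 1000,
    base_seed: int = 0,
    *,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Score every sample (column) of an expression matrix.

    Per-sample RNG seeds are derived deterministically from ``base_seed``
    and the sample id, so the result is reproducible and invariant to the
    column order.  A sample that fails (e.g. insufficient signature
    overlap) is reported as NaN with a warning rather than aborting the
    cohort.

    Returns
    -------
    DataFrame indexed by sample id with columns ``s_plus``, ``s_minus``,
    ``score``, ``overlap_fraction``, ``seed``.
    """
    rows = []
    for sid in x.columns:
        seed = sample_seed(base_seed, sid)
        try:
            r = score_sample(
                x[sid], sig, n_perm=n_perm, seed=seed, min_overlap=min_overlap
            )
            rows.append((sid, r.s_plus, r.s_minus, r.score, r.overlap_fraction, seed))
        except ValueError as err:
            warnings.warn(f"sample {sid!r} not scored: {err}")
            rows.append((sid, np.nan, np.nan, np.nan, np.nan, seed))
    out = pd.DataFrame(
        rows, columns=["sample_id", "s_plus", "s_minus", "score", "overlap_fraction", "seed"]
    ).set_index("sample_id")
    return out


def infiltration_scores(
    x: pd.DataFrame,
    profiles: Mapping[str, WeightedSignature],
    n_perm: int = 1000,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Apply the scoring engine to a set of named weight profiles.

    Used with externally supplied immune-cell weight profiles (e.g. naive
    B, memory B, CD8+ T, CD4+ T, NK, myeloid) to estimate relative
    infiltration levels; this module does not derive such base profiles.
    """
    out = pd.DataFrame(index=pd.Index(x.columns, name="sample_id"))
    for name, sig in profiles.items():
        out[name] = score_cohort(x, sig, n_perm=n_perm, base_seed=base_seed)["score"]
    return out


class EnrichmentScorer(TransformerMixin, BaseEstimator):
    """Transform expression profiles into signature enrichment scores.

    scikit-learn style transformer over :func:`score_cohort`: ``transform``
    takes a samples x genes DataFrame and returns one score column per
    signature, so scores can feed directly into downstream sklearn
    pipelines and model selection.

    Parameters
    ----------
    signatures :
        A single :class:`WeightedSignature` or a mapping name -> signature.
    n_perm : int
        Permutations for the null (>= 100, default 1000).
    random_state : int
        Base seed; per-sample seeds are derived from it and the sample id.
    min_overlap : float
        Minimum fraction of signature genes a sample must contain.
    """

    def __init__(
        self,
        signatures: WeightedSignature | Mapping[str, WeightedSignature] | None = None,
        *,
        n_perm: int = 1000,
        random_state: int = 0,
        min_overlap: float = 0.5,
    ):
        self.signatures = signatures
        self.n_perm = n_perm
        self.random_state = random_state
        self.min_overlap = min_overlap

    def _sig_map(self) -> dict[str, WeightedSignature]:
        if self.signatures is None:
            raise ValueError("no signatures supplied")
        if isinstance(self.signatures, WeightedSignature):
            name = self.signatures.target_subtype or "signature"
            return {name: self.signatures}
        return dict(self.signatures)

    def fit(self, X: pd.DataFrame, y=None) -> "EnrichmentScorer":
        self.signatures_ = self._sig_map()
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame")
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "signatures_"):
            self.fit(X)
        x = X.T
        out = pd.DataFrame(index=pd.Index(X.index, name="sample_id"))
        for name, sig in self.signatures_.items():
            out[name] = score_cohort(
                x,
                sig,
                n_perm=self.n_perm,
                base_seed=self.random_state,
                min_overlap=self.min_overlap,
            )["score"]
        return out

    def score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full per-signature score table (s_plus, s_minus, score, overlap)."""
        if not hasattr(self, "signatures_"):
            self.fit(X)
        parts = {
            name: score_cohort(
                X.T,
                sig,
                n_perm=self.n_perm,
                base_seed=self.random_state,
                min_overlap=self.min_overlap,
            )
            for name, sig in self.signatures_.items()
        }
        return pd.concat(parts, axis=1, names=["signature", "metric"])
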