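"""Config-driven orchestration: build signatures, score, report.

A run is described by a plain YAML mapping (paths plus numeric
parameters); unknown keys are rejected so typos fail loudly.  Every
output directory receives a ``manifest.json`` with the fully resolved
configuration, because permutation-based scores are not reproducible
without the recorded seed.  Manifests contain no timestamps: two runs
with identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import associations as assoc
from . import io as hio
from .signature import build_weighted_signature, differential_expression
from .scoring import score_cohort

__all__ = ["PipelineConfig", "run_build", "run_score", "run_report"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


@dataclass
class PipelineConfig:
    """Validated parameters of a pipeline run."""

    expression: str | None = None
    annotation: str | None = None
    signatures: list[str] = field(default_factory=list)
    survival: str | None = None
    features: str | None = None
    drug: str | None = None
    response: str | None = None
    out_dir: str = "histosig_out"
    targets: list[str] = field(default_factory=lambda: ["lepidic", "solid"])
    trim_cap: float = 10.0
    test: str = "student"
    log_base: str = "e"
    rescale: str = "cap"
    n_perm: int = 1000
    seed: int = 17
    min_overlap: float = 0.5
    dichotomize: str = "median"
    min_count: int = 20
    alpha: float = 0.01

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(mapping) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a key-value mapping")
        return cls.from_mapping(data)

    def validate(self) -> None:
        if not self.trim_cap > 0:
            raise ValueError("trim_cap must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0 < self.min_overlap <= 1:
            raise ValueError("min_overlap must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.test not in ("student", "welch"):
            raise ValueError("test must be 'student' or 'welch'")
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")
        if self.dichotomize not in ("median", "zero"):
            raise ValueError("dichotomize must be 'median' or 'zero'")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must lie in [0, 2^31)")


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise ValueError(f"config is missing the {what} path")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def _write_manifest(cfg: PipelineConfig, out: Path, step: str) -> None:
    manifest = {"step": step, "config": asdict(cfg)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _read_annotation(path: Path) -> pd.Series:
    ann = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ann.iloc[:, 0].astype(str)


def run_build(config: PipelineConfig | dict) -> dict[str, Path]:
    """Differential profiles and weighted signatures for each target subtype.

    Writes, under ``out_dir``: ``profile_<subtype>.tsv`` (gene, t, p, fdr),
    ``signature_<subtype>.tsv`` and ``manifest.json``.  Returns the map
    subtype -> signature path.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_mapping(config)
    x = hio.read_expression_table(_require(cfg.expression, "expression"))
    ann = _read_annotation(_require(cfg.annotation, "annotation"))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    for target in cfg.targets:
        prof = differential_expression(x, ann, target, test=cfg.test)
        prof.to_csv(out / f"profile_{target}.tsv", sep="\t", float_format=_FLOAT_FMT)
        sig = build_weighted_signature(
            prof, cfg.trim_cap, log_base=cfg.log_base, target_subtype=target
        )
        sig_path = out / f"signature_{target}.tsv"
        hio.write_signature(sig, sig_path)
        paths[target] = sig_path
        logger.info("built signature for %s (%d genes)", target, len(sig))
    _write_manifest(cfg, out, "build")
    return paths


def run_score(config: PipelineConfig | dict) -> pd.DataFrame:
    """Score a cohort with every configured signature; write ``scores.tsv``.

    The output table has one row per sample and, per signature name,
    columns ``<name>_s_plus``, ``<name>_s_minus``, ``<name>_score`` and
    ``<name>_overlap``.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_mapping(config)
    x = hio.read_expression_table(_require(cfg.expression, "expression"))
    if not cfg.signatures:
        raise ValueError("config lists no signature files")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames = []
    for sig_path in cfg.signatures:
        sig = hio.read_signature(_require(sig_path, "signature"))
        name = sig.target_subtype or Path(sig_path).stem
        tab = score_cohort(
            x, sig, n_perm=cfg.n_perm, base_seed=cfg.seed, min_overlap=cfg.min_overlap
        )
        tab = tab.drop(columns="seed").rename(
            columns={
                "s_plus": f"{name}_s_plus",
                "s_minus": f"{name}_s_minus",
                "score": f"{name}_score",
                "overlap_fraction": f"{name}_overlap",
            }
        )
        frames.append(tab)
    scores = pd.concat(frames, axis=1)
    scores.to_csv(out / "scores.tsv", sep="\t", float_format=_FLOAT_FMT)
    _write_manifest(cfg, out, "score")
    return scores


def _score_columns(scores: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        c[: -len("_score")]: scores[c] for c in scores.columns if c.endswith("_score")
    }


def run_report(config: PipelineConfig | dict, *, plots: bool = True) -> dict:
    """Join scores to outcomes and run every configured association.

    Requires ``expression`` plus ``signatures``; optional ``survival``,
    ``features``, ``drug`` and ``response`` tables trigger the matching
    analyses (absent tables are skipped with a logged notice).  All
    results are computed before anything is written, so a failure leaves
    no partial outputs.  Emits one TSV per analysis, ``summary.txt`` and,
    when ``plots`` is set, Kaplan-Meier and ROC figures.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_mapping(config)
    scores = run_score(cfg)
    out = Path(cfg.out_dir)
    per_sig = _score_columns(scores)

    results: dict = {"scores": scores}
    summary: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    figures: list = []

    if cfg.survival:
        surv = pd.read_csv(_require(cfg.survival, "survival"), sep=None, engine="python", index_col=0)
        results["survival"] = {}
        for name, s in per_sig.items():
            groups = assoc.dichotomize(s, cfg.dichotomize)
            chi2, p = assoc.logrank_test(groups, surv)
            cox = assoc.cox_regression(s, surv, score_name=f"{name}_score")
            results["survival"][name] = {"logrank_chi2": chi2, "logrank_p": p, "cox": cox}
            tables[f"cox_{name}.tsv"] = cox
            summary.append(
                f"survival\t{name}\tn={len(s)}\tlog-rank chi2={chi2:.4g}\tp={p:.4g}"
            )
            if plots:
                figures.append(("km", name, groups, surv))
    else:
        logger.info("no survival table configured; survival section skipped")

    if cfg.features:
        feats = pd.read_csv(_require(cfg.features, "features"), sep=None, engine="python", index_col=0)
        results["features"] = {}
        for name, s in per_sig.items():
            res = assoc.feature_association(s, feats, cfg.min_count, cfg.alpha)
            results["features"][name] = res
            tables[f"features_{name}.tsv"] = res
            summary.append(
                f"features\t{name}\tn={len(s)}\ttested={len(res)}\t"
                f"significant={int(res['significant'].sum())}\talpha={cfg.alpha}"
            )

    if cfg.drug:
        drug = pd.read_csv(_require(cfg.drug, "drug"), sep=None, engine="python", index_col=0).iloc[:, 0]
        results["drug"] = {}
        for name, s in per_sig.items():
            rho, p = assoc.rank_correlation(s, drug)
            results["drug"][name] = {"rho": rho, "p": p}
            summary.append(f"drug\t{name}\tn={len(s)}\tspearman rho={rho:.4g}\tp={p:.4g}")

    if cfg.response:
        resp = pd.read_csv(_require(cfg.response, "response"), sep=None, engine="python", index_col=0).iloc[:, 0]
        results["response"] = {}
        for name, s in per_sig.items():
            roc = assoc.response_classification(s, resp)
            results["response"][name] = roc
            summary.append(
                f"response\t{name}\tn={roc.n_pos + roc.n_neg}\tAUC={roc.auc:.4g}\t"
                f"wilcoxon p={roc.p_wilcoxon:.4g}"
            )
            if plots:
                figures.append(("roc", name, roc, None))

    for fname, tab in tables.items():
        tab.to_csv(out / fname, sep="\t", float_format=_FLOAT_FMT)
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    if plots and figures:
        _render_figures(figures, out)
    _write_manifest(cfg, out, "report")
    return results


def _render_figures(figures: list, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    for kind, name, a, b in figures:
        fig, ax = plt.subplots(figsize=(4.5, 4))
        if kind == "km":
            groups, surv = a, b
            for label, mask in (("high", a.astype(bool)), ("low", ~a.astype(bool))):
                km = KaplanMeierFitter()
                km.fit(surv.loc[mask, "time"], surv.loc[mask, "event"], label=f"{name} {label}")
                km.plot_survival_function(ax=ax)
            ax.set_xlabel("time (months)")
            ax.set_ylabel("survival probability")
            fig.savefig(out / f"km_{name}.png", dpi=120, bbox_inches="tight")
        else:
            roc = a
            ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f}")
            ax.plot([0, 1], [0, 1], ls="--", c="grey")
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.legend()
            fig.savefig(out / f"roc_{name}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
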