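"""Reading and writing expression tables, probe-level data and signatures.

All formats are plain delimited text: expression tables are TSV/CSV with
one identifier column and a header of sample ids; signatures are
three-column TSV with a comment header carrying the trim cap and target
subtype.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import WeightedSignature

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_table",
    "sniff_delimiter",
    "collapse_probesets",
    "write_signature",
    "read_signature",
]

logger = logging.getLogger(__name__)


def sniff_delimiter(path) -> str:
    """Guess tab vs comma from the first non-comment line."""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValueError(f"empty file: {path}")


def read_table(path, **kwargs) -> pd.DataFrame:
    """Delimited text -> DataFrame with exact (round-trip) float parsing."""
    return pd.read_csv(
        path,
        sep=sniff_delimiter(path),
        index_col=0,
        comment="#",
        float_precision="round_trip",
        **kwargs,
    )


def _validate_expression(x: pd.DataFrame) -> pd.DataFrame:
    if x.index.has_duplicates:
        raise ValueError("duplicate gene ids after collapse")
    if x.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"expression matrix too small: shape {x.shape}")
    if x.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return x


def read_expression_table(
    path, orientation: str = "genes-in-rows", *, sep: str | None = None
) -> pd.DataFrame:
    """Read a delimited expression table into a genes x samples DataFrame.

    Rows containing any missing value are dropped (logged); duplicate gene
    rows are collapsed by keeping the row with the largest mean across
    samples, mirroring the probeset-collapse rule.

    Parameters
    ----------
    path :
        Tab- or comma-delimited text file with one header row and one
        identifier column (delimiter sniffed when ``sep`` is None).
    orientation :
        ``"genes-in-rows"`` (default) or ``"samples-in-rows"``.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    x = pd.read_csv(
        path,
        sep=sep if sep is not None else sniff_delimiter(path),
        index_col=0,
        comment="#",
        float_precision="round_trip",
    )
    if orientation == "samples-in-rows":
        x = x.T
    x = x.apply(pd.to_numeric, errors="coerce")

    n_na = int(x.isna().any(axis=1).sum())
    if n_na:
        logger.info("dropping %d rows with missing values from %s", n_na, path)
        x = x.dropna(axis=0)
    if len(x) == 0:
        raise ValueError(f"all rows dropped while reading {path}")

    if x.index.has_duplicates:
        means = x.mean(axis=1)
        order = np.lexsort((x.index.to_numpy(str), -means.to_numpy()))
        x = x.iloc[order]
        x = x[~x.index.duplicated(keep="first")].sort_index()
    x.index.name = "gene"
    return _validate_expression(x)


def write_expression_table(x: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV (full float precision)."""
    x.to_csv(path, sep="\t", float_format="%.17g")


def collapse_probesets(
    probe_values: pd.DataFrame,
    probe_to_gene: Mapping[str, str] | pd.Series,
    method: str = "max_intensity",
) -> pd.DataFrame:
    """Collapse probe-level intensities to one row per gene.

    ``max_intensity`` (the one-channel microarray convention) keeps, for
    each gene, the single probe with the largest mean intensity across
    samples; ``average`` (two-channel) returns the per-sample mean over
    the gene's probes.  Probes without a gene mapping are dropped.
    """
    if method not in ("max_intensity", "average"):
        raise ValueError(f"unknown collapse method {method!r}")
    mapping = pd.Series(dict(probe_to_gene) if not isinstance(probe_to_gene, pd.Series) else probe_to_gene)
    mapping = mapping.dropna()
    if mapping.empty:
        raise ValueError("empty probe-to-gene map")
    kept = probe_values.index.intersection(mapping.index)
    n_drop = len(probe_values) - len(kept)
    if n_drop:
        logger.info("dropping %d unmapped probes", n_drop)
    pv = probe_values.loc[kept]
    genes = mapping.loc[kept]

    if method == "average":
        out = pv.groupby(genes.to_numpy()).mean()
    else:
        means = pv.mean(axis=1)
        # deterministic winner: largest mean, ties by probe id
        order = np.lexsort((pv.index.to_numpy(str), -means.to_numpy()))
        pv_sorted = pv.iloc[order]
        genes_sorted = genes.iloc[order]
        first = ~genes_sorted.duplicated(keep="first")
        out = pv_sorted[first.to_numpy()]
        out.index = genes_sorted[first.to_numpy()].to_numpy()
        out = out.sort_index()
    out.index.name = "gene"
    return out


def write_signature(sig: WeightedSignature, path) -> None:
    """Write a signature as three-column TSV with a comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# histosig weighted signature\n")
        fh.write(f"# target_subtype: {sig.target_subtype or ''}\n")
        fh.write(f"# trim_cap: {sig.trim_cap!r}\n")
        fh.write("gene\tw_plus\tw_minus\n")
        for gene, wp, wm in sig.weights[["w_plus", "w_minus"]].itertuples():
            fh.write(f"{gene}\t{wp!r}\t{wm!r}\n")


def read_signature(path) -> WeightedSignature:
    """Read a signature written by :func:`write_signature`.

    Round-trips are value-exact: weights are printed with ``repr`` so the
    parsed floats are bit-identical.  Invariant violations in the file
    (weights outside [0, 1], a gene with both weights positive) raise.
    """
    path = Path(path)
    trim_cap = 10.0
    target: str | None = None
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# trim_cap:"):
                trim_cap = float(line.split(":", 1)[1])
            elif line.startswith("# target_subtype:"):
                target = line.split(":", 1)[1].strip() or None
    w = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    if list(w.columns) != ["w_plus", "w_minus"]:
        raise ValueError(f"malformed signature file {path}: columns {list(w.columns)}")
    return WeightedSignature(w, trim_cap=trim_cap, target_subtype=target)
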