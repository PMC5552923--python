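"""Readers and writers for the formats the framework touches.

Newick trees (via dendropy), delimited crossing tables and labelled
square matrices (via pandas), and JSON fit reports.  Taxon labels are
matched case-sensitively after trimming whitespace and replacing
internal spaces with underscores — the Newick convention — since
crossing tables are joined to trees by name.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ricomp.model_build import CrossingDataset
from ricomp.posterior import HPDInterval, Summary, SummaryRow
from ricomp.relatedness import Phylogeny

__all__ = [
    "TableSchema",
    "read_cross_table",
    "read_fit_report",
    "read_newick",
    "read_square_matrix",
    "write_fit_report",
    "write_newick",
]

logger = logging.getLogger(__name__)


@dataclass
class TableSchema:
    """Column roles of a crossing table."""

    maternal_col: str
    paternal_col: str
    response_cols: list[str]
    continuous_cols: list[str] = field(default_factory=list)
    categorical_cols: list[str] = field(default_factory=list)
    delimiter: str | None = None  # None = auto-detect comma vs tab

    def __post_init__(self) -> None:
        if self.maternal_col == self.paternal_col:
            raise ValueError("maternal and paternal columns must differ")
        if not self.response_cols:
            raise ValueError("at least one response column is required")
        if self.delimiter is not None and self.delimiter not in (",", "\t"):
            raise ValueError("delimiter must be ',' or a tab (or None to detect)")


def read_newick(path: str | Path, assume_unit_lengths: bool = False) -> Phylogeny:
    """Read one rooted Newick tree, validating labels and branch lengths.

    Duplicate tip labels, unparseable strings and negative branch
    lengths all raise.  Missing branch lengths are an error — the
    relatedness matrix is meaningless without them — unless
    ``assume_unit_lengths`` fills them with 1.  Polytomies are kept
    as-is.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    tree.is_rooted = True

    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
    if dupes:
        raise ValueError(f"duplicate tip labels in {path}: {dupes}")
    normalized = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise ValueError(f"unlabelled tip in {path}")
        clean = "_".join(leaf.taxon.label.strip().split())
        normalized[leaf.taxon.label] = clean
        leaf.taxon.label = clean

    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge length is irrelevant
        if edge.length is None:
            if assume_unit_lengths:
                edge.length = 1.0
            else:
                raise ValueError(
                    f"missing branch length in {path}; pass "
                    "assume_unit_lengths=True to treat all branches as 1"
                )
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length} in {path}")
    return tree


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    """Write a tree as a single Newick string with branch lengths."""
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _sniff_delimiter(path: Path) -> str:
    with path.open() as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValueError(
        f"could not detect a comma or tab delimiter in {path}; "
        "set TableSchema.delimiter explicitly"
    )


def read_cross_table(path: str | Path, schema: TableSchema) -> CrossingDataset:
    """Read a delimited crossing table into a :class:`CrossingDataset`.

    Rows with a missing response value are dropped with a logged count.
    Responses far outside the nominal RI range warn (indices can
    slightly exceed [0, 1], e.g. with heterospecific advantage, but
    values outside [-1, 1.5] usually indicate a parsing problem).
    Non-numeric entries in declared continuous predictors raise with
    the offending row number.
    """
    path = Path(path)
    sep = schema.delimiter or _sniff_delimiter(path)
    table = pd.read_csv(path, sep=sep)
    declared = [
        schema.maternal_col,
        schema.paternal_col,
        *schema.response_cols,
        *schema.continuous_cols,
        *schema.categorical_cols,
    ]
    missing = [c for c in declared if c not in table.columns]
    if missing:
        raise KeyError(f"declared columns absent from {path}: {missing}")

    for col in schema.continuous_cols + schema.response_cols:
        parsed = pd.to_numeric(table[col], errors="coerce")
        bad = parsed.isna() & table[col].notna()
        if col in schema.continuous_cols and bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {table[col].iloc[row]!r} in continuous "
                f"column {col!r} at data row {row + 1}"
            )
        table[col] = parsed

    n_file = len(table)
    keep = table[schema.response_cols].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "dropped %d of %d rows with missing response values", dropped, n_file
        )
    table = table.loc[keep]

    resp = table[schema.response_cols].to_numpy(dtype=float)
    if resp.size and ((resp < -1.0) | (resp > 1.5)).any():
        warnings.warn(
            "response values outside [-1, 1.5] found; RI indices can "
            "slightly exceed [0, 1] but values this extreme are suspicious",
            stacklevel=2,
        )

    return CrossingDataset(
        table=table,
        maternal_col=schema.maternal_col,
        paternal_col=schema.paternal_col,
        response_cols=schema.response_cols,
        continuous_cols=schema.continuous_cols,
        categorical_cols=schema.categorical_cols,
    )


def read_square_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a labelled square matrix (first row and column are labels).

    Asymmetry up to 1e-8 is accepted silently; up to 1e-3 the matrix is
    symmetrized by averaging with a warning; beyond that it is an
    error.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    M = pd.read_csv(path, sep=sep, index_col=0)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"non-square matrix in {path}: shape {M.shape}")
    M.index = M.index.astype(str)
    M.columns = M.columns.astype(str)
    if list(M.index) != list(M.columns):
        raise ValueError(f"row and column labels differ in {path}")
    body = M.to_numpy(dtype=float)
    asym = float(np.max(np.abs(body - body.T))) if body.size else 0.0
    if asym > 1e-3:
        raise ValueError(
            f"matrix in {path} is asymmetric (max deviation {asym:.2g})"
        )
    if asym > 1e-8:
        warnings.warn(
            f"matrix in {path} is slightly asymmetric (max deviation "
            f"{asym:.2g}); symmetrized by averaging",
            stacklevel=2,
        )
        body = (body + body.T) / 2.0
        M = pd.DataFrame(body, index=M.index, columns=M.columns)
    return M


def write_fit_report(summary: Summary, path: str | Path) -> None:
    """Serialize a fit summary to machine-readable JSON.

    One record per parameter/contrast (mean, mode, HPD bounds, PSRF,
    excludes-zero flag) plus the run metadata (seeds, iterations, prior
    settings) attached by ``fit``.  The file round-trips through
    :func:`read_fit_report`.
    """
    if not summary.rows:
        raise ValueError("no draws: summary has no parameter rows")
    payload = {
        "parameters": [
            {
                "name": r.name,
                "kind": r.kind,
                "mean": r.mean,
                "mode": r.mode,
                "hpd_lower": r.hpd.lower,
                "hpd_upper": r.hpd.upper,
                "prob": r.hpd.prob,
                "psrf": r.psrf,
                "excludes_zero": bool(r.excludes_zero),
            }
            for r in summary.rows
        ],
        "multivariate_psrf": summary.multivariate_psrf,
        "meta": summary.meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def read_fit_report(path: str | Path) -> Summary:
    """Read a JSON fit report back into a :class:`Summary`."""
    with open(path) as fh:
        payload = json.load(fh)
    rows = [
        SummaryRow(
            name=rec["name"],
            kind=rec["kind"],
            mean=rec["mean"],
            mode=rec["mode"],
            hpd=HPDInterval(rec["hpd_lower"], rec["hpd_upper"], rec["prob"]),
            psrf=rec["psrf"],
            excludes_zero=rec["excludes_zero"],
        )
        for rec in payload["parameters"]
    ]
    return Summary(
        rows=rows,
        multivariate_psrf=payload.get("multivariate_psrf"),
        meta=payload.get("meta", {}),
    )
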