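"""Readers and writers for the standard inputs and tabular outputs.

Formats: newick for the tree; tab-separated UTF-8 text for the OTU count
table, the sample-to-group map and the taxonomy table.  Lines starting
with ``#`` are treated as comments in every TSV.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grouping import Grouping
from .tree import PhyloTree

__all__ = [
    "parse_tree",
    "parse_count_table",
    "parse_grouping",
    "parse_taxonomy",
    "load_tree",
    "load_count_table",
    "load_grouping",
    "load_taxonomy",
    "write_tree",
    "write_count_table",
    "write_grouping",
    "write_taxonomy",
    "write_json",
]

_TSV = dict(sep="\t", comment="#", encoding="utf-8")


def parse_tree(newick_text: str) -> PhyloTree:
    """Parse a rooted newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(newick_text)


def parse_count_table(tsv_text: str) -> pd.DataFrame:
    """Parse an OTU-by-sample read-count TSV.

    First column holds OTU ids, header row holds sample ids, cells are
    nonnegative integers.  Returns a DataFrame indexed by OTU id with one
    integer column per sample, in input order.
    """
    try:
        df = pd.read_csv(_io.StringIO(tsv_text), index_col=0, **_TSV)
    except Exception as exc:
        raise ValidationError(f"cannot parse count table: {exc}") from exc
    return validate_count_table(df)


def validate_count_table(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate OTU ids: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dup}")
    values = df.to_numpy()
    if values.size == 0:
        raise ValidationError("empty count table")
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count table cells must be numeric")
    if np.any(~np.isfinite(values.astype(float))):
        raise ValidationError("count table contains missing/non-finite cells")
    if np.any(values < 0):
        raise ValidationError("negative read counts")
    if np.any(values != np.floor(values)):
        raise ValidationError("read counts must be integers")
    out = df.astype(np.int64)
    out.index.name = "otu_id"
    zero = out.columns[out.sum(axis=0) == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total reads: {zero}")
    return out


def parse_grouping(tsv_text: str, samples: list[str] | None = None) -> Grouping:
    """Parse a two-column sample→group TSV (header optional).

    When ``samples`` is given, every listed sample must be mapped.
    Groups are ordered by first appearance; weights default to 1/G.
    """
    df = pd.read_csv(_io.StringIO(tsv_text), header=None, dtype=str, **_TSV)
    if df.shape[1] < 2:
        raise ValidationError("grouping TSV needs two columns: sample, group")
    first = [str(x).lower() for x in df.iloc[0, :2]]
    if first in (["sample", "group"], ["#sample", "group"]):
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    grouping = Grouping.from_mapping(mapping)
    if samples is not None:
        grouping.require_samples(samples)
    return grouping


def parse_taxonomy(tsv_text: str) -> pd.DataFrame:
    """Parse an OTU taxonomy TSV: otu_id, lineage string, confidence.

    Lineage strings are semicolon-separated rank names (classifier
    output); confidence must lie in [0, 1].
    """
    df = pd.read_csv(
        _io.StringIO(tsv_text),
        header=None,
        names=["otu_id", "lineage", "confidence"],
        dtype={"otu_id": str, "lineage": str},
        **_TSV,
    )
    first = str(df.iloc[0, 0]).lower() if len(df) else ""
    if first in ("otu_id", "otu"):
        df = df.iloc[1:]
    df = df.set_index("otu_id")
    if df["lineage"].isna().any() or (df["lineage"].astype(str).str.strip() == "").any():
        raise ValidationError("missing lineage string")
    try:
        df["confidence"] = df["confidence"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric confidence: {exc}") from exc
    bad = df.index[(df["confidence"] < 0) | (df["confidence"] > 1)].tolist()
    if bad:
        raise ValidationError(f"confidence outside [0, 1] for: {bad}")
    return df


# ----------------------------------------------------------------------
# path-based convenience loaders / writers
# ----------------------------------------------------------------------

def load_tree(path) -> PhyloTree:
    return parse_tree(Path(path).read_text(encoding="utf-8"))


def load_count_table(path) -> pd.DataFrame:
    return parse_count_table(Path(path).read_text(encoding="utf-8"))


def load_grouping(path, samples=None) -> Grouping:
    return parse_grouping(Path(path).read_text(encoding="utf-8"), samples)


def load_taxonomy(path) -> pd.DataFrame:
    return parse_taxonomy(Path(path).read_text(encoding="utf-8"))


def write_tree(tree: PhyloTree, path, name_internal: bool = True) -> None:
    Path(path).write_text(tree.to_newick(name_internal=name_internal) + "\n", encoding="utf-8")


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="otu_id")


def write_grouping(grouping: Grouping, path) -> None:
    lines = ["sample\tgroup"] + [f"{s}\t{g}" for s, g in grouping.sample_to_group.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", header=False, index_label="otu_id")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
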