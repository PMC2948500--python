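"""Readers and writers for the pipeline's on-disk artifacts.

All artifacts are plain text: expression matrices and annotation tables as
TSV, pathway dictionaries as GMT, ground truth and reports as JSON.

An expression matrix is a :class:`pandas.DataFrame` of non-negative linear
intensities with probe identifiers on the index and sample identifiers on the
columns.  A probe annotation table has columns ``probe_id``, ``gene_symbol``
and ``is_chrY`` (0/1); a sample annotation table has ``sample_id``, ``group``,
``sex``, ``arm`` and optionally ``tumor_content_percent``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "validate_expression_matrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_gmt",
    "write_gmt",
    "read_json",
    "write_json",
]


def validate_expression_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix contract and return the input unchanged.

    Raises ``ValueError`` on duplicate probe/sample identifiers, non-finite
    entries or negative intensities.
    """
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids: {dup[:5]}")
    if m.columns.has_duplicates:
        dup = m.columns[m.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup[:5]}")
    values = m.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative intensities")
    return m


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    return validate_expression_matrix(m.astype(float))


def write_expression_tsv(m: pd.DataFrame, path: str | Path) -> None:
    validate_expression_matrix(m)
    m.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return annot.set_index("sample_id")


def write_sample_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index_label="sample_id")


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    annot["is_chrY"] = annot["is_chrY"].astype(int)
    return annot.set_index("probe_id")


def write_probe_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index_label="probe_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping of set name -> member list.

    The second (description) column is ignored on read.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, _desc, *members = fields
            if name in sets:
                raise ValueError(f"duplicate gene set name: {name}")
            sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
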