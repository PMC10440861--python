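"""Channel x sample count matrices and their TSV dialect.

The on-disk format mirrors the standard mutational-matrix layout: a
tab-separated table whose first column, headed ``MutationType``, holds
the channel labels, followed by one integer column per sample.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import SCHEMAS

MUTATION_TYPE_COL = "MutationType"


class ChannelMatrix:
    """Non-negative integer count matrix with a fixed canonical row order.

    Parameters
    ----------
    counts
        DataFrame indexed by channel label with one column per sample.
        Rows may arrive in any order but the label set must equal the
        canonical set of the schema exactly.
    schema
        ``"cnv48"`` or ``"sv32"``.
    """

    def __init__(self, counts: pd.DataFrame, schema: str):
        if schema not in SCHEMAS:
            raise ValueError(f"unknown schema: {schema!r}")
        canonical = SCHEMAS[schema]
        labels = list(counts.index)
        extra = [lab for lab in labels if lab not in set(canonical)]
        if extra:
            raise ValueError(f"unknown channel label: {extra[0]!r}")
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate channel labels")
        if set(labels) != set(canonical):
            missing = sorted(set(canonical) - set(labels))
            raise ValueError(f"missing channel label: {missing[0]!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = counts.reindex(list(canonical))
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any():
            raise ValueError("counts must be non-negative integers")
        if not np.array_equal(arr, np.round(arr)):
            raise ValueError("counts must be integer-valued")
        self.df = values.astype(np.int64)
        self.df.index.name = MUTATION_TYPE_COL
        self.schema = schema

    # -- construction -----------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        per_sample: Mapping[str, Counter],
        schema: str,
        samples: Iterable[str] | None = None,
    ) -> "ChannelMatrix":
        """Build a matrix from per-sample channel counters.

        ``samples`` fixes the column order and may add all-zero columns
        for samples without events; by default columns follow the
        mapping's insertion order.
        """
        cols = list(samples) if samples is not None else list(per_sample)
        for s in per_sample:
            if s not in cols:
                cols.append(s)
        canonical = SCHEMAS[schema]
        data = {
            s: [per_sample.get(s, Counter()).get(ch, 0) for ch in canonical]
            for s in cols
        }
        df = pd.DataFrame(data, index=list(canonical))
        return cls(df, schema)

    # -- properties --------------------------------------------------------

    @property
    def channel_labels(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def column(self, sample: str) -> pd.Series:
        if sample not in self.df.columns:
            raise KeyError(f"unknown sample: {sample!r}")
        return self.df[sample]

    def total(self) -> int:
        return int(self.df.to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChannelMatrix):
            return NotImplemented
        return self.schema == other.schema and self.df.equals(other.df)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ChannelMatrix(schema={self.schema!r}, "
            f"channels={len(self.df)}, samples={len(self.df.columns)})"
        )

    # -- I/O ---------------------------------------------------------------

    def write(self, path: str | Path) -> Path:
        """Write the matrix as a MutationType-keyed TSV."""
        path = Path(path)
        self.df.to_csv(path, sep="\t")
        return path


def write_matrix(matrix: ChannelMatrix, path: str | Path) -> Path:
    return matrix.write(path)


def read_matrix(path: str | Path) -> ChannelMatrix:
    """Read a matrix TSV, auto-detecting the schema from its labels.

    Rows may appear in any order; they are restored to canonical order.
    A label outside both schemas is a fatal error naming the label.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != MUTATION_TYPE_COL:
        raise ValueError(
            f"expected first column {MUTATION_TYPE_COL!r}, got {df.index.name!r}"
        )
    labels = set(df.index)
    for schema, canonical in SCHEMAS.items():
        if labels == set(canonical):
            return ChannelMatrix(df, schema)
    # Name the first label that belongs to neither schema; if labels are
    # a strict subset, name the first missing one instead.
    known = set(SCHEMAS["cnv48"]) | set(SCHEMAS["sv32"])
    offending = [lab for lab in df.index if lab not in known]
    if offending:
        raise ValueError(f"unknown channel label: {offending[0]!r}")
    schema = "cnv48" if labels <= set(SCHEMAS["cnv48"]) else "sv32"
    missing = sorted(set(SCHEMAS[schema]) - labels)
    raise ValueError(f"missing channel label: {missing[0]!r}")
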