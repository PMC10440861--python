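"""Allele-specific copy-number segment classification (CNV48).

Reads segmentation tables from the common allele-specific CNV callers
(ASCAT, ABSOLUTE, Sequenza, FACETS, Battenberg, PURPLE) or a generic
5+-column layout, classifies every segment into one of 48 channels by
heterozygosity state, total copy number and segment size, and builds
channel x sample count matrices.

Coordinates are treated as 1-based inclusive throughout; segment length
is ``end - start + 1``.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .channels import cnv_size_bin, tcn_class
from .genome import normalize_chrom
from .matrix import ChannelMatrix

logger = logging.getLogger(__name__)


@dataclass
class CNVSegment:
    """One allele-specific copy-number segment of one sample.

    ``major_cn``/``minor_cn`` are the integer copy counts of the major
    (A) and minor (B) allele, with ``major_cn >= minor_cn >= 0``.
    """

    sample: str
    chromosome: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start: {self.start}-{self.end}"
            )
        if not (self.major_cn >= self.minor_cn >= 0):
            raise ValueError(
                f"require major_cn >= minor_cn >= 0, got "
                f"({self.major_cn}, {self.minor_cn})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tcn(self) -> int:
        return self.major_cn + self.minor_cn


class CNV48Channel(NamedTuple):
    tcn_class: str
    het_state: str
    size_bin: str

    @property
    def label(self) -> str:
        return f"{self.tcn_class}:{self.het_state}:{self.size_bin}"


def normalize_alleles(cn_a: float, cn_b: float) -> tuple[int, int]:
    """Round caller allele copy numbers and order them (major, minor).

    Fractional values (PURPLE, Battenberg) round half away from zero.
    Negative or non-finite input is a validation error.
    """
    out = []
    for v in (cn_a, cn_b):
        v = float(v)
        if not math.isfinite(v):
            raise ValueError(f"non-finite copy number: {v}")
        if v < 0:
            raise ValueError(f"negative copy number: {v}")
        out.append(math.floor(v + 0.5))
    return max(out), min(out)


def classify_cnv_segment(seg: CNVSegment) -> CNV48Channel:
    """Assign a segment to its CNV48 channel.

    Heterozygosity state: homdel (A = B = 0), LOH (A > 0, B = 0), or
    het (A > 0, B > 0). The TCN class is the binned total copy number
    and the size bin depends on the state (homdel uses 3 bins).
    """
    if seg.major_cn == 0:
        state = "homdel"
    elif seg.minor_cn == 0:
        state = "LOH"
    else:
        state = "het"
    return CNV48Channel(tcn_class(seg.tcn), state, cnv_size_bin(seg.length, state))


# --------------------------------------------------------------------------
# Caller dialects
# --------------------------------------------------------------------------

# Column mappings per caller; FACETS derives the major allele as
# tcn.em - lcn.em and is handled specially.
_DIALECT_COLUMNS: dict[str, dict[str, str]] = {
    "GENERIC": {"chrom": "chrom", "start": "start", "end": "end",
                "a": "major_cn", "b": "minor_cn"},
    "ASCAT": {"chrom": "chr", "start": "startpos", "end": "endpos",
              "a": "nMajor", "b": "nMinor"},
    "ABSOLUTE": {"chrom": "Chromosome", "start": "Start", "end": "End",
                 "a": "Modal_HSCN_1", "b": "Modal_HSCN_2"},
    "SEQUENZA": {"chrom": "chromosome", "start": "start.pos", "end": "end.pos",
                 "a": "A", "b": "B"},
    "BATTENBERG": {"chrom": "chr", "start": "startpos", "end": "endpos",
                   "a": "nMaj1_A", "b": "nMin1_A"},
    "PURPLE": {"chrom": "chromosome", "start": "start", "end": "end",
               "a": "majorAlleleCopyNumber", "b": "minorAlleleCopyNumber"},
}
_FACETS_COLUMNS = {"chrom": "chrom", "start": "start", "end": "end",
                   "tcn": "tcn.em", "lcn": "lcn.em"}

DIALECTS: tuple[str, ...] = (
    "ASCAT", "ABSOLUTE", "SEQUENZA", "FACETS", "BATTENBERG", "PURPLE", "GENERIC",
)


def _required_columns(dialect: str) -> list[str]:
    if dialect == "FACETS":
        cols = _FACETS_COLUMNS
        return [cols["chrom"], cols["start"], cols["end"], cols["tcn"], cols["lcn"]]
    cols = _DIALECT_COLUMNS[dialect]
    return [cols["chrom"], cols["start"], cols["end"], cols["a"], cols["b"]]


def read_segmentation(
    path: str | Path,
    dialect: str = "GENERIC",
    sample: str | None = None,
) -> list[CNVSegment]:
    """Read a tab-separated segmentation table in a caller dialect.

    Rows failing validation (bad chromosome, end <= start, missing or
    invalid copy numbers) are skipped with a logged warning. A missing
    mandatory column is fatal; so is a file with no valid rows.

    ``sample`` supplies the sample id when the file has no ``sample``
    column (single-sample caller outputs).
    """
    dialect = dialect.upper()
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    for col in _required_columns(dialect):
        if col not in df.columns:
            raise ValueError(
                f"{dialect} segmentation file is missing mandatory column {col!r}"
            )
    has_sample_col = "sample" in df.columns
    if not has_sample_col and sample is None:
        raise ValueError(
            "segmentation file has no 'sample' column and no sample name was given"
        )

    segments: list[CNVSegment] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        try:
            seg = _parse_row(row, dialect, sample if not has_sample_col else None)
        except (ValueError, TypeError) as exc:
            logger.warning("skipping row %s: %s", idx, exc)
            n_skipped += 1
            continue
        segments.append(seg)
    if n_skipped:
        logger.warning("skipped %d invalid row(s) in %s", n_skipped, path)
    if not segments:
        raise ValueError(f"no valid segments in {path}")
    return segments


def _parse_row(row: pd.Series, dialect: str, sample_override: str | None) -> CNVSegment:
    if dialect == "FACETS":
        cols = _FACETS_COLUMNS
        lcn = row[cols["lcn"]]
        tcn = row[cols["tcn"]]
        if pd.isna(lcn):
            raise ValueError("FACETS minor allele copy number (lcn.em) is missing")
        if pd.isna(tcn):
            raise ValueError("FACETS total copy number (tcn.em) is missing")
        cn_a, cn_b = float(tcn) - float(lcn), float(lcn)
    else:
        cols = _DIALECT_COLUMNS[dialect]
        cn_a, cn_b = row[cols["a"]], row[cols["b"]]
        if pd.isna(cn_a) or pd.isna(cn_b):
            raise ValueError("missing allele copy number")
    chrom = normalize_chrom(row[cols["chrom"]])
    if chrom is None:
        raise ValueError(f"chromosome {row[cols['chrom']]!r} outside 1-22/X/Y")
    major, minor = normalize_alleles(float(cn_a), float(cn_b))
    sample_id = sample_override if sample_override is not None else str(row["sample"])
    return CNVSegment(
        sample=sample_id,
        chromosome=chrom,
        start=int(row[cols["start"]]),
        end=int(row[cols["end"]]),
        major_cn=major,
        minor_cn=minor,
    )


def write_segmentation(
    segments: Sequence[CNVSegment], path: str | Path, dialect: str = "GENERIC"
) -> Path:
    """Write segments as a tab-separated table in a caller dialect.

    Used by the fixture generator and round-trip tests; every dialect
    written here reads back to the identical segment list.
    """
    dialect = dialect.upper()
    path = Path(path)
    rows = []
    for seg in segments:
        if dialect == "FACETS":
            cols = _FACETS_COLUMNS
            rec = {
                "sample": seg.sample,
                cols["chrom"]: seg.chromosome,
                cols["start"]: seg.start,
                cols["end"]: seg.end,
                cols["tcn"]: seg.major_cn + seg.minor_cn,
                cols["lcn"]: seg.minor_cn,
            }
        else:
            cols = _DIALECT_COLUMNS[dialect]
            rec = {
                "sample": seg.sample,
                cols["chrom"]: seg.chromosome,
                cols["start"]: seg.start,
                cols["end"]: seg.end,
                cols["a"]: seg.major_cn,
                cols["b"]: seg.minor_cn,
            }
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def build_cnv_matrix(
    segments: Sequence[CNVSegment], samples: Iterable[str] | None = None
) -> ChannelMatrix:
    """Count classified segments into a 48 x samples matrix.

    Column sums equal each sample's input segment count; ``samples``
    may add all-zero columns and fix the column order.
    """
    if not segments and samples is None:
        raise ValueError("no segments and no sample list given")
    per_sample: dict[str, Counter] = {}
    for seg in segments:
        per_sample.setdefault(seg.sample, Counter())[
            classify_cnv_segment(seg).label
        ] += 1
    return ChannelMatrix.from_counts(per_sample, "cnv48", samples=samples)


def cnv_matrix_from_file(
    path: str | Path, dialect: str = "GENERIC", sample: str | None = None
) -> ChannelMatrix:
    """Convenience pipeline: read a segmentation file and build the matrix."""
    return build_cnv_matrix(read_segmentation(path, dialect=dialect, sample=sample))
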