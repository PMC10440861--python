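"""Structural-variant classification (SV32).

Reads rearrangements from BEDPE, infers the event type from mate
strands when no ``svclass`` is given, annotates every record as
clustered or non-clustered from the inter-mutational distance (IMD) of
its breakpoints, and classifies each record into one of 32 channels.

Clustering follows the Potts-filter procedure: each chromosome's
breakpoint IMD series (log10-transformed) is segmented by exact
piecewise-constant fitting, and a segment is clustered when it holds at
least ``min_breakpoints`` breakpoints whose mean raw IMD is at least
``cluster_factor``-fold below the sample's mean IMD. A record is
clustered when either of its breakpoints falls in a clustered segment.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import sv_size_bin
from .genome import normalize_chrom
from .matrix import ChannelMatrix
from .pcf import pcf_segment

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 25.0
DEFAULT_CLUSTER_FACTOR = 10.0
DEFAULT_MIN_BREAKPOINTS = 10

SV_CLASS_SYNONYMS: dict[str, str] = {
    "del": "del", "deletion": "del",
    "tds": "tds", "dup": "tds", "duplication": "tds",
    "tandem-duplication": "tds", "tandem_duplication": "tds",
    "tandem-dup": "tds", "tandemdup": "tds",
    "inv": "inv", "inversion": "inv",
    "trans": "trans", "tra": "trans", "translocation": "trans", "bnd": "trans",
}


@dataclass
class SVRecord:
    """One structural variant: two breakpoints, strands, optional class."""

    sample: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str | None = None
    strand2: str | None = None
    svclass: str | None = None
    clustered: bool = False

    @property
    def intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def size(self) -> int | None:
        """Event size in bp; defined only for intra-chromosomal records."""
        return abs(self.pos2 - self.pos1) if self.intra else None


@dataclass
class Breakpoint:
    """A single genomic position contributed by an SVRecord."""

    chromosome: str
    position: int
    parent: SVRecord
    imd: float = np.nan
    clustered: bool = False


def normalize_svclass(token: object) -> str | None:
    """Map an svclass token to {del, tds, inv, trans}; None if unknown."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    return SV_CLASS_SYNONYMS.get(str(token).strip().lower())


def infer_svclass(chrom1: str, chrom2: str, strand1: str, strand2: str) -> str:
    """Infer the SV type from the mate-pair strand convention.

    Mates on different chromosomes are translocations; on the same
    chromosome the convention is deletion (+/+), tandem duplication
    (-/-), and inversion (+/- or -/+).
    """
    if strand1 not in "+-" or strand2 not in "+-":
        raise ValueError(f"invalid strands: ({strand1!r}, {strand2!r})")
    if chrom1 != chrom2:
        return "trans"
    if strand1 == strand2:
        return "del" if strand1 == "+" else "tds"
    return "inv"


# --------------------------------------------------------------------------
# BEDPE input
# --------------------------------------------------------------------------

_BEDPE_REQUIRED = ("chrom1", "start1", "end1", "chrom2", "start2", "end2")


def read_bedpe(path: str | Path, sample: str | None = None) -> list[SVRecord]:
    """Read structural variants from a BEDPE table.

    Each mate interval is collapsed to a point: BEDPE 0-based half-open
    starts are converted to 1-based and the midpoint is taken with
    floor. The file must carry either an ``svclass`` column or both
    strand columns; rows where neither yields a class are skipped with
    a warning. ``sample`` names single-sample files lacking a
    ``sample`` column (default "Sample1").
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _BEDPE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"BEDPE file is missing mandatory column(s): {missing}")
    has_class = "svclass" in df.columns
    has_strands = "strand1" in df.columns and "strand2" in df.columns
    if not has_class and not has_strands:
        raise ValueError(
            "BEDPE file must carry either an 'svclass' column or both "
            "'strand1' and 'strand2' columns"
        )
    has_sample_col = "sample" in df.columns
    default_sample = sample if sample is not None else "Sample1"

    records: list[SVRecord] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        try:
            records.append(
                _parse_bedpe_row(row, has_class, has_strands,
                                 row["sample"] if has_sample_col else default_sample)
            )
        except (ValueError, TypeError) as exc:
            logger.warning("skipping BEDPE row %s: %s", idx, exc)
            n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d invalid row(s) in %s", n_skipped, path)
    if not records:
        raise ValueError(f"no valid SV records in {path}")
    return records


def _mate_position(start: object, end: object) -> int:
    start, end = int(start), int(end)
    # 1-based inclusive interval is [start+1, end]; midpoint with floor.
    return (start + 1 + end) // 2


def _parse_bedpe_row(
    row: pd.Series, has_class: bool, has_strands: bool, sample_id: object
) -> SVRecord:
    chrom1 = normalize_chrom(row["chrom1"])
    chrom2 = normalize_chrom(row["chrom2"])
    if chrom1 is None or chrom2 is None:
        raise ValueError(
            f"chromosome outside 1-22/X/Y: ({row['chrom1']!r}, {row['chrom2']!r})"
        )
    pos1 = _mate_position(row["start1"], row["end1"])
    pos2 = _mate_position(row["start2"], row["end2"])

    strand1 = strand2 = None
    if has_strands and not (pd.isna(row["strand1"]) or pd.isna(row["strand2"])):
        strand1, strand2 = str(row["strand1"]), str(row["strand2"])

    svclass = normalize_svclass(row["svclass"]) if has_class else None
    if has_class and not pd.isna(row.get("svclass")) and svclass is None:
        raise ValueError(f"unknown svclass token: {row['svclass']!r}")
    if svclass is None:
        if strand1 is None or strand2 is None:
            raise ValueError("record has neither a usable svclass nor both strands")
        svclass = infer_svclass(chrom1, chrom2, strand1, strand2)
    if chrom1 != chrom2 and svclass != "trans":
        logger.warning(
            "inter-chromosomal record annotated %r reclassified as trans", svclass
        )
        svclass = "trans"
    rec = SVRecord(
        sample=str(sample_id), chrom1=chrom1, pos1=pos1,
        chrom2=chrom2, pos2=pos2, strand1=strand1, strand2=strand2,
        svclass=svclass,
    )
    if rec.intra and rec.size == 0:
        raise ValueError("intra-chromosomal record with zero size")
    return rec


def write_bedpe(records: Sequence[SVRecord], path: str | Path) -> Path:
    """Write records as BEDPE with single-base mate intervals.

    Positions round-trip exactly: a point p is written as
    (start, end) = (p - 1, p).
    """
    rows = []
    for r in records:
        rows.append({
            "chrom1": r.chrom1, "start1": r.pos1 - 1, "end1": r.pos1,
            "chrom2": r.chrom2, "start2": r.pos2 - 1, "end2": r.pos2,
            "strand1": r.strand1 or ".", "strand2": r.strand2 or ".",
            "svclass": r.svclass, "sample": r.sample,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# --------------------------------------------------------------------------
# Inter-mutational distance and clustering
# --------------------------------------------------------------------------

def compute_imd(positions: Sequence[int]) -> np.ndarray:
    """Inter-mutational distances of position-sorted breakpoints.

    imd[i] = positions[i] - positions[i-1] for i >= 1; the first
    breakpoint takes the distance to its successor so it can join a
    cluster at the chromosome edge. A single breakpoint has no defined
    IMD (returned as NaN; excluded from all means).
    """
    p = np.asarray(positions, dtype=float)
    if p.size == 0:
        raise ValueError("no breakpoints")
    if np.any(np.diff(p) < 0):
        raise ValueError("positions must be sorted")
    if p.size == 1:
        return np.array([np.nan])
    imd = np.empty(p.size)
    imd[1:] = np.diff(p)
    imd[0] = imd[1]
    return imd


def extract_breakpoints(records: Sequence[SVRecord]) -> list[Breakpoint]:
    """Both mates of every record, one Breakpoint each (single sample)."""
    bps = []
    for rec in records:
        bps.append(Breakpoint(rec.chrom1, rec.pos1, rec))
        bps.append(Breakpoint(rec.chrom2, rec.pos2, rec))
    return bps


def _annotate_one_sample(
    records: Sequence[SVRecord],
    gamma: float,
    cluster_factor: float,
    min_breakpoints: int,
) -> list[Breakpoint]:
    for rec in records:
        rec.clustered = False
    bps = extract_breakpoints(records)
    by_chrom: dict[str, list[Breakpoint]] = {}
    for bp in bps:
        by_chrom.setdefault(bp.chromosome, []).append(bp)
    all_imds: list[np.ndarray] = []
    for chrom_bps in by_chrom.values():
        chrom_bps.sort(key=lambda b: b.position)
        imds = compute_imd([b.position for b in chrom_bps])
        for bp, d in zip(chrom_bps, imds):
            bp.imd = float(d)
        if len(chrom_bps) >= 2:
            all_imds.append(imds)
    if not all_imds:
        return bps
    sample_mean = float(np.concatenate(all_imds).mean())
    threshold = sample_mean / cluster_factor
    for chrom_bps in by_chrom.values():
        if len(chrom_bps) < 2:
            continue
        imds = np.array([b.imd for b in chrom_bps])
        seg = pcf_segment(np.log10(imds + 1.0), gamma)
        for start, stop in seg.segments():
            count = stop - start
            if count >= min_breakpoints and imds[start:stop].mean() <= threshold:
                for bp in chrom_bps[start:stop]:
                    bp.clustered = True
                    bp.parent.clustered = True
    return bps


def annotate_clustered(
    records: Sequence[SVRecord],
    gamma: float = DEFAULT_GAMMA,
    cluster_factor: float = DEFAULT_CLUSTER_FACTOR,
    min_breakpoints: int = DEFAULT_MIN_BREAKPOINTS,
) -> list[Breakpoint]:
    """Set the ``clustered`` flag on every record, grouping by sample.

    Returns the per-breakpoint annotation (positions, IMDs, flags) for
    downstream rainfall plotting. Samples with fewer than two
    breakpoints on every chromosome are entirely non-clustered.
    """
    by_sample: dict[str, list[SVRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample, []).append(rec)
    bps: list[Breakpoint] = []
    for sample_records in by_sample.values():
        bps.extend(
            _annotate_one_sample(sample_records, gamma, cluster_factor,
                                 min_breakpoints)
        )
    return bps


# --------------------------------------------------------------------------
# Channel assignment and matrix
# --------------------------------------------------------------------------

def classify_sv(record: SVRecord, clustered: bool | None = None) -> str:
    """SV32 channel label of a record (translocations are unbinned)."""
    if record.svclass not in ("del", "tds", "inv", "trans"):
        raise ValueError(f"record has no canonical svclass: {record.svclass!r}")
    state = record.clustered if clustered is None else clustered
    prefix = "clustered" if state else "non-clustered"
    if record.svclass == "trans":
        return f"{prefix}_trans"
    size = record.size
    if size is None:
        raise ValueError("intra-chromosomal class on inter-chromosomal record")
    return f"{prefix}_{record.svclass}_{sv_size_bin(size)}"


def build_sv_matrix(
    records: Sequence[SVRecord], samples: Iterable[str] | None = None
) -> ChannelMatrix:
    """Count classified records into a 32 x samples matrix."""
    if not records and samples is None:
        raise ValueError("no records and no sample list given")
    per_sample: dict[str, Counter] = {}
    for rec in records:
        per_sample.setdefault(rec.sample, Counter())[classify_sv(rec)] += 1
    return ChannelMatrix.from_counts(per_sample, "sv32", samples=samples)


def sv_matrix_from_bedpe(
    path: str | Path,
    sample: str | None = None,
    gamma: float = DEFAULT_GAMMA,
    cluster_factor: float = DEFAULT_CLUSTER_FACTOR,
    min_breakpoints: int = DEFAULT_MIN_BREAKPOINTS,
) -> ChannelMatrix:
    """Convenience pipeline: BEDPE -> clustered annotation -> SV32 matrix."""
    records = read_bedpe(path, sample=sample)
    annotate_clustered(records, gamma=gamma, cluster_factor=cluster_factor,
                       min_breakpoints=min_breakpoints)
    return build_sv_matrix(records)
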