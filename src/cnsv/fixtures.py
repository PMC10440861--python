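"""Synthetic segmentation and BEDPE fixtures with known ground truth.

Each generator emits an input file in a supported dialect together
with a sidecar recording the intended channel of every record, so the
whole pipeline (reader -> classifier -> matrix) can be checked exactly
without external data.

CNV scenarios emulate archetypal tumor copy-number profiles:

* ``focal_amp`` — many highly amplified focal segments (ecDNA-like):
  60% of events drawn from TCN 5-8 / 9+ channels at sizes up to
  1Mb-10Mb, 40% diploid-range background.
* ``loh_heavy`` — extensive loss of heterozygosity, dominated by
  TCN = 1 LOH segments across all size bins.
* ``wgd`` — whole-genome duplication: TCN 3-4 segments in the largest
  (10Mb-40Mb, >40Mb) size bins.

SV scenarios emulate rearrangement dispersal patterns:

* ``chromothripsis`` — one tight breakpoint cluster (>= 10 breakpoints
  spaced ~1 kb inside a 1 Mb window on a dedicated chromosome) plus
  sparse background events spaced >= 10 Mb elsewhere; the spacing ratio
  guarantees the 10-fold IMD threshold holds with a wide margin.
* ``dispersed`` — only sparse events (at most 4 events, i.e. 8
  breakpoints, per chromosome, so the >= 10-breakpoint rule alone
  forbids clustered calls).
* ``mixed`` — a cluster plus a richer background including
  translocations.

Identical (scenario, n_events, seed) specs produce byte-identical
files.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CNVSegment, write_segmentation
from .genome import AUTOSOMES, CHROM_LENGTHS
from .sv import SVRecord, write_bedpe

CNV_SCENARIOS = ("focal_amp", "loh_heavy", "wgd")
SV_SCENARIOS = ("chromothripsis", "dispersed", "mixed")
SCENARIOS = CNV_SCENARIOS + SV_SCENARIOS

# Size ranges sampled strictly inside each bin (bp, inclusive).
_CNV_SIZE_RANGES = {
    "0-100kb": (10_000, 100_000),
    "100kb-1Mb": (100_001, 1_000_000),
    "1Mb-10Mb": (1_000_001, 10_000_000),
    "10Mb-40Mb": (10_000_001, 40_000_000),
    ">40Mb": (40_000_001, 80_000_000),
    ">1Mb": (1_000_001, 20_000_000),
}
_SV_SIZE_RANGES = {
    "0-10kb": (1_000, 10_000),
    "10-100kb": (10_001, 100_000),
    "100kb-1Mb": (100_001, 1_000_000),
    "1Mb-10Mb": (1_000_001, 10_000_000),
    ">10Mb": (10_000_001, 30_000_000),
}

_TCN_CHOICES = {"1": (1,), "2": (2,), "3-4": (3, 4),
                "5-8": (5, 6, 7, 8), "9+": (9, 10, 11, 12, 14, 16)}

SIGNATURE_FRACTION = 0.6  # signature-pool share of events per scenario

_STRANDS = {"del": ("+", "+"), "tds": ("-", "-"), "inv": ("+", "-")}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    scenario: str
    n_events: int = 20
    seed: int = 0
    sample_id: str = "Sample1"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario: {self.scenario!r}")
        if self.n_events < 1:
            raise ValueError("n_events must be positive")
        if self.scenario in ("chromothripsis", "mixed") and self.n_events < 8:
            raise ValueError(
                f"{self.scenario} requires n_events >= 8 "
                "(a >=10-breakpoint cluster plus background)"
            )


@dataclass
class FixtureResult:
    """Generated input file plus its ground truth."""

    path: Path
    truth_path: Path
    meta_path: Path
    truth: pd.DataFrame  # record_id, intended_channel [, clustered]
    counts: Counter  # intended channel -> count

    @property
    def n_records(self) -> int:
        return len(self.truth)


def _write_sidecars(
    spec: FixtureSpec, out_dir: Path, stem: str, truth: pd.DataFrame
) -> tuple[Path, Path]:
    truth_path = out_dir / f"{stem}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    meta_path = out_dir / f"{stem}.meta.json"
    meta_path.write_text(json.dumps({
        "scenario": spec.scenario, "n_events": spec.n_events,
        "seed": spec.seed, "sample_id": spec.sample_id,
    }, indent=2) + "\n")
    return truth_path, meta_path


# --------------------------------------------------------------------------
# CNV fixtures
# --------------------------------------------------------------------------

def _cnv_pools(scenario: str, rng: np.random.Generator):
    """Return (signature_template, background_template) sampling closures.

    Templates are (tcn_class, het_state, size_bin) triples.
    """
    background = [
        ("2", "het"), ("3-4", "het"), ("1", "LOH"), ("2", "LOH"),
    ]
    five_bins = ("0-100kb", "100kb-1Mb", "1Mb-10Mb", "10Mb-40Mb", ">40Mb")

    def bg() -> tuple[str, str, str]:
        tcn, state = background[rng.integers(len(background))]
        return tcn, state, five_bins[rng.integers(len(five_bins))]

    if scenario == "focal_amp":
        small = ("0-100kb", "100kb-1Mb", "1Mb-10Mb")

        def sig() -> tuple[str, str, str]:
            tcn = ("5-8", "9+")[rng.integers(2)]
            state = "het" if rng.random() < 0.7 else "LOH"
            return tcn, state, small[rng.integers(3)]

    elif scenario == "loh_heavy":

        def sig() -> tuple[str, str, str]:
            tcn = "1" if rng.random() < 0.8 else "2"
            return tcn, "LOH", five_bins[rng.integers(len(five_bins))]

    else:  # wgd
        big = ("10Mb-40Mb", ">40Mb")

        def sig() -> tuple[str, str, str]:
            return "3-4", "het", big[rng.integers(2)]

    return sig, bg


def _place_segment(
    cursors: dict[str, int], order: list[str], size: int, start_at: list[int]
) -> tuple[str, int, int]:
    """Place a segment of the given size on the first chromosome with room."""
    gap = 10_000
    for _ in range(len(order)):
        chrom = order[start_at[0] % len(order)]
        start_at[0] += 1
        start = cursors[chrom]
        end = start + size - 1
        if end <= CHROM_LENGTHS[chrom] - 1_000_000:
            cursors[chrom] = end + gap + 1
            return chrom, start, end
    raise ValueError("n_events exceeds placeable capacity of the genome")


def generate_cnv_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureResult:
    """Emit a GENERIC-dialect segmentation file realizing the scenario.

    Segments are non-overlapping on chromosomes 1-22; the sidecar holds
    each segment's intended CNV48 channel, which classification must
    reproduce exactly.
    """
    if spec.scenario not in CNV_SCENARIOS:
        raise ValueError(f"not a CNV scenario: {spec.scenario!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    sig, bg = _cnv_pools(spec.scenario, rng)
    n_sig = math.ceil(SIGNATURE_FRACTION * spec.n_events)
    templates = [sig() for _ in range(n_sig)]
    templates += [bg() for _ in range(spec.n_events - n_sig)]

    order = list(AUTOSOMES)
    rng.shuffle(order)
    cursors = {c: 1_000_000 for c in order}
    rr = [0]
    segments: list[CNVSegment] = []
    labels: list[str] = []
    for tcn_cls, state, size_bin in templates:
        lo, hi = _CNV_SIZE_RANGES[size_bin]
        size = int(rng.integers(lo, hi + 1))
        if state == "homdel":
            major = minor = 0
        else:
            tcn = int(_TCN_CHOICES[tcn_cls][rng.integers(len(_TCN_CHOICES[tcn_cls]))])
            if state == "LOH":
                major, minor = tcn, 0
            else:
                minor = int(rng.integers(1, tcn // 2 + 1))
                major = tcn - minor
        chrom, start, end = _place_segment(cursors, order, size, rr)
        segments.append(CNVSegment(spec.sample_id, chrom, start, end, major, minor))
        labels.append(f"{tcn_cls}:{state}:{size_bin}")

    stem = f"{spec.scenario}_n{spec.n_events}_s{spec.seed}"
    path = out_dir / f"{stem}.seg.tsv"
    write_segmentation(segments, path, dialect="GENERIC")
    truth = pd.DataFrame({
        "record_id": [f"cnv_{i:04d}" for i in range(len(labels))],
        "intended_channel": labels,
    })
    truth_path, meta_path = _write_sidecars(spec, out_dir, stem, truth)
    return FixtureResult(path, truth_path, meta_path, truth, Counter(labels))


# --------------------------------------------------------------------------
# SV fixtures
# --------------------------------------------------------------------------

class _BackgroundPlacer:
    """Sparse breakpoint placement: >= 10 Mb spacing, <= 8 breakpoints
    per chromosome so background segments can never satisfy the
    >= 10-breakpoint cluster rule."""

    MAX_BP = 8

    def __init__(self, chroms: list[str], rng: np.random.Generator):
        self.rng = rng
        self.chroms = chroms
        self.cursors = {c: 5_000_000 + int(rng.integers(0, 10_000_000))
                        for c in chroms}
        self.bp_count = {c: 0 for c in chroms}
        self._rr = 0

    def _spacing(self) -> int:
        return 10_000_000 + int(self.rng.integers(0, 5_000_000))

    def _candidates(self, need_bp: int, room: int):
        for _ in range(len(self.chroms)):
            c = self.chroms[self._rr % len(self.chroms)]
            self._rr += 1
            if self.bp_count[c] + need_bp <= self.MAX_BP and (
                self.cursors[c] + room <= CHROM_LENGTHS[c] - 2_000_000
            ):
                yield c

    def place_intra(self, size: int) -> tuple[str, int, int]:
        for c in self._candidates(2, size):
            pos1 = self.cursors[c]
            pos2 = pos1 + size
            self.cursors[c] = pos2 + self._spacing()
            self.bp_count[c] += 2
            return c, pos1, pos2
        raise ValueError("n_events exceeds placeable capacity of the genome")

    def place_trans(self) -> tuple[str, int, str, int]:
        picks: list[tuple[str, int]] = []
        for c in self._candidates(1, 0):
            if picks and picks[0][0] == c:
                continue
            picks.append((c, self.cursors[c]))
            if len(picks) == 2:
                break
        if len(picks) < 2:
            raise ValueError("n_events exceeds placeable capacity of the genome")
        for c, _ in picks:
            self.cursors[c] += self._spacing()
            self.bp_count[c] += 1
        return picks[0][0], picks[0][1], picks[1][0], picks[1][1]


def _make_record(
    sample: str, svtype: str, chrom1: str, pos1: int, chrom2: str, pos2: int
) -> SVRecord:
    if svtype == "trans":
        s1, s2 = "+", "-"
    else:
        s1, s2 = _STRANDS[svtype]
    return SVRecord(sample=sample, chrom1=chrom1, pos1=pos1,
                    chrom2=chrom2, pos2=pos2, strand1=s1, strand2=s2,
                    svclass=svtype)


def generate_sv_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureResult:
    """Emit a BEDPE file realizing the scenario, with ground truth.

    Cluster scenarios place consecutive breakpoints ~1 kb apart on a
    dedicated chromosome while all background spacing is >= 10 Mb (and
    background intra-event sizes >= 1 Mb), so the cluster's mean IMD
    sits far more than ten-fold below the sample mean and the pipeline
    must flag exactly the cluster records as clustered.
    """
    if spec.scenario not in SV_SCENARIOS:
        raise ValueError(f"not an SV scenario: {spec.scenario!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    has_cluster = spec.scenario in ("chromothripsis", "mixed")
    cluster_frac = {"chromothripsis": 0.6, "mixed": 0.5, "dispersed": 0.0}
    n_cluster = 0
    if has_cluster:
        n_cluster = max(5, round(cluster_frac[spec.scenario] * spec.n_events))
        n_cluster = min(n_cluster, spec.n_events - 2)
    n_bg = spec.n_events - n_cluster

    records: list[SVRecord] = []
    labels: list[str] = []
    clustered_truth: list[bool] = []

    cluster_chrom: str | None = None
    if has_cluster:
        big = [c for c in AUTOSOMES[:12]]
        cluster_chrom = big[int(rng.integers(len(big)))]
        pos = 20_000_000 + int(rng.integers(0, 20_000_000))
        positions = []
        for _ in range(2 * n_cluster):
            positions.append(pos)
            pos += int(rng.integers(800, 1201))
        intra_types = ("del", "tds", "inv")
        for i in range(n_cluster):
            p1, p2 = positions[2 * i], positions[2 * i + 1]
            svtype = intra_types[int(rng.integers(3))]
            records.append(_make_record(spec.sample_id, svtype,
                                        cluster_chrom, p1, cluster_chrom, p2))
            labels.append(f"clustered_{svtype}_0-10kb")
            clustered_truth.append(True)

    bg_chroms = [c for c in AUTOSOMES if c != cluster_chrom]
    placer = _BackgroundPlacer(bg_chroms, rng)
    # Cluster scenarios keep background IMDs >= 1 Mb so the sample mean
    # stays far above 10x the cluster spacing; dispersed may use any size.
    if has_cluster:
        bg_bins = ("1Mb-10Mb", ">10Mb")
    else:
        bg_bins = tuple(_SV_SIZE_RANGES)
    trans_p = {"chromothripsis": 0.0, "mixed": 0.25, "dispersed": 0.25}[spec.scenario]
    intra_types = ("del", "tds", "inv")
    for _ in range(n_bg):
        if rng.random() < trans_p:
            c1, p1, c2, p2 = placer.place_trans()
            records.append(_make_record(spec.sample_id, "trans", c1, p1, c2, p2))
            labels.append("non-clustered_trans")
        else:
            svtype = intra_types[int(rng.integers(3))]
            size_bin = bg_bins[int(rng.integers(len(bg_bins)))]
            lo, hi = _SV_SIZE_RANGES[size_bin]
            size = int(rng.integers(lo, hi + 1))
            c, p1, p2 = placer.place_intra(size)
            records.append(_make_record(spec.sample_id, svtype, c, p1, c, p2))
            labels.append(f"non-clustered_{svtype}_{size_bin}")
        clustered_truth.append(False)

    stem = f"{spec.scenario}_n{spec.n_events}_s{spec.seed}"
    path = out_dir / f"{stem}.bedpe"
    write_bedpe(records, path)
    truth = pd.DataFrame({
        "record_id": [f"sv_{i:04d}" for i in range(len(labels))],
        "intended_channel": labels,
        "clustered": clustered_truth,
    })
    truth_path, meta_path = _write_sidecars(spec, out_dir, stem, truth)
    return FixtureResult(path, truth_path, meta_path, truth, Counter(labels))


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureResult:
    """Dispatch to the CNV or SV generator by scenario."""
    if spec.scenario in CNV_SCENARIOS:
        return generate_cnv_fixture(spec, out_dir)
    return generate_sv_fixture(spec, out_dir)
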