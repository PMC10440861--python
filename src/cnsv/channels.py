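"""Canonical channel schemas for large mutational events.

Two fixed classification schemas are defined here:

* **CNV48** — 48 mutually exclusive channels for allele-specific
  copy-number segments, split by heterozygosity state (homozygous
  deletion / LOH / heterozygous), total copy number (TCN) class, and
  segment size.
* **SV32** — 32 channels for structural variants, split by clustered
  status, event type (del / tds / inv / trans), and event size
  (translocations are not size-binned).

All size bins are left-open, right-closed: a 100 kb segment falls in
the 0-100kb bin, a 100 kb + 1 bp segment in the next one.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# CNV48
# --------------------------------------------------------------------------

TCN_CLASSES: tuple[str, ...] = ("0", "1", "2", "3-4", "5-8", "9+")
HET_TCN_CLASSES: tuple[str, ...] = ("2", "3-4", "5-8", "9+")
LOH_TCN_CLASSES: tuple[str, ...] = ("1", "2", "3-4", "5-8", "9+")

CNV_SIZE_BINS: tuple[str, ...] = (
    "0-100kb", "100kb-1Mb", "1Mb-10Mb", "10Mb-40Mb", ">40Mb",
)
HOMDEL_SIZE_BINS: tuple[str, ...] = ("0-100kb", "100kb-1Mb", ">1Mb")

HET_STATES: tuple[str, ...] = ("homdel", "LOH", "het")


def tcn_class(tcn: int) -> str:
    """Map a total copy number to its class label."""
    if tcn < 0:
        raise ValueError(f"negative total copy number: {tcn}")
    if tcn <= 2:
        return str(tcn)
    if tcn <= 4:
        return "3-4"
    if tcn <= 8:
        return "5-8"
    return "9+"


def cnv_size_bin(length: int, het_state: str) -> str:
    """Bin a segment length (bp) for the given heterozygosity state.

    Homozygous deletions use the coarser 3-bin set; het/LOH segments
    use the 5-bin set.
    """
    if length <= 0:
        raise ValueError(f"non-positive segment length: {length}")
    if length <= 100_000:
        return "0-100kb"
    if length <= 1_000_000:
        return "100kb-1Mb"
    if het_state == "homdel":
        return ">1Mb"
    if length <= 10_000_000:
        return "1Mb-10Mb"
    if length <= 40_000_000:
        return "10Mb-40Mb"
    return ">40Mb"


def _cnv48_channel_order() -> tuple[str, ...]:
    # homdel block (3), LOH block (25), het block (20); each ordered by
    # TCN class then size bin.
    labels = [f"0:homdel:{b}" for b in HOMDEL_SIZE_BINS]
    labels += [f"{t}:LOH:{b}" for t in LOH_TCN_CLASSES for b in CNV_SIZE_BINS]
    labels += [f"{t}:het:{b}" for t in HET_TCN_CLASSES for b in CNV_SIZE_BINS]
    return tuple(labels)


CNV48_CHANNELS: tuple[str, ...] = _cnv48_channel_order()
assert len(CNV48_CHANNELS) == 48

# --------------------------------------------------------------------------
# SV32
# --------------------------------------------------------------------------

SV_TYPES: tuple[str, ...] = ("del", "tds", "inv", "trans")
SV_SIZE_BINS: tuple[str, ...] = (
    "0-10kb", "10-100kb", "100kb-1Mb", "1Mb-10Mb", ">10Mb",
)
CLUSTER_STATES: tuple[str, ...] = ("clustered", "non-clustered")


def sv_size_bin(size: int) -> str:
    """Bin an intra-chromosomal SV size (bp)."""
    if size <= 0:
        raise ValueError(f"non-positive SV size: {size}")
    if size <= 10_000:
        return "0-10kb"
    if size <= 100_000:
        return "10-100kb"
    if size <= 1_000_000:
        return "100kb-1Mb"
    if size <= 10_000_000:
        return "1Mb-10Mb"
    return ">10Mb"


def _sv32_channel_order() -> tuple[str, ...]:
    labels = []
    for state in CLUSTER_STATES:
        for svtype in ("del", "tds", "inv"):
            labels += [f"{state}_{svtype}_{b}" for b in SV_SIZE_BINS]
        labels.append(f"{state}_trans")
    return tuple(labels)


SV32_CHANNELS: tuple[str, ...] = _sv32_channel_order()
assert len(SV32_CHANNELS) == 32

SCHEMAS: dict[str, tuple[str, ...]] = {
    "cnv48": CNV48_CHANNELS,
    "sv32": SV32_CHANNELS,
}
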