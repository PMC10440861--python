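"""Human reference genome constants (GRCh38 chromosome lengths)."""

from __future__ import annotations

# GRCh38 primary-assembly chromosome lengths in bp.
CHROM_LENGTHS: dict[str, int] = {
    "1": 248_956_422,
    "2": 242_193_529,
    "3": 198_295_559,
    "4": 190_214_555,
    "5": 181_538_259,
    "6": 170_805_979,
    "7": 159_345_973,
    "8": 145_138_636,
    "9": 138_394_717,
    "10": 133_797_422,
    "11": 135_086_622,
    "12": 133_275_309,
    "13": 114_364_328,
    "14": 107_043_718,
    "15": 101_991_189,
    "16": 90_338_345,
    "17": 83_257_441,
    "18": 80_373_285,
    "19": 58_617_616,
    "20": 64_444_167,
    "21": 46_709_983,
    "22": 50_818_468,
    "X": 156_040_895,
    "Y": 57_227_415,
}

VALID_CHROMS = frozenset(CHROM_LENGTHS)

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))


def normalize_chrom(label: object) -> str | None:
    """Normalize a chromosome label to "1".."22", "X", "Y".

    A leading "chr" (any case) is stripped; numeric labels such as the
    float 1.0 produced by table parsers are accepted. Returns None for
    labels outside the human schema (contigs, MT, ...).
    """
    if isinstance(label, float) and label.is_integer():
        label = int(label)
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s.endswith(".0"):
        s = s[:-2]
    return s if s in VALID_CHROMS else None
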