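"""miRNA target-set intersection and canonical seed-match scanning.

Seed sites follow the canonical taxonomy: with miRNA nucleotides numbered
from its 5' end, the seed hexamer pairs positions 2–7.  Written 5'->3' on
the UTR, a site is classified by whether the base 5' of the hexamer match
pairs miRNA position 8 (m8) and whether the base 3' of it is an adenosine
(A1):

    8mer      rc(m2..m8) + 'A'   (8 nt)
    7mer-m8   rc(m2..m8)         (7 nt)
    7mer-A1   rc(m2..m7) + 'A'   (7 nt)
    6mer      rc(m2..m7)         (6 nt)

Each seed-hexamer locus yields exactly one site of the longest applicable
type; coordinates are 1-based inclusive on the UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


@dataclass(frozen=True)
class TargetPredictionSet:
    """miRNA ids (or target gene ids) predicted by one source."""

    source_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if any(not m for m in self.members):
            raise ValueError(f"{self.source_name}: empty id in target set")

    @classmethod
    def from_ids(cls, source_name: str, ids: Iterable[str]) -> "TargetPredictionSet":
        return cls(source_name, frozenset(ids))


@dataclass
class VennResult:
    """Intersection of >= 2 prediction sets with all exclusive region counts.

    ``region_counts`` maps each non-empty source combination (sorted tuple
    of source names) to the number of ids found in exactly those sources.
    """

    common: set[str]
    region_counts: dict[tuple[str, ...], int]
    set_sizes: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sources": "&".join(combo), "n_sources": len(combo), "count": n}
            for combo, n in sorted(self.region_counts.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows, columns=["sources", "n_sources", "count"])


def intersect_target_sets(sets: Sequence[TargetPredictionSet]) -> VennResult:
    """Common ids across all sets plus every exclusive Venn region count."""
    if len(sets) < 2:
        raise ValueError("need at least 2 target sets to intersect")
    names = [s.source_name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate source names")
    common = set(sets[0].members)
    for s in sets[1:]:
        common &= s.members
    region_counts: dict[tuple[str, ...], int] = {
        combo: 0
        for k in range(1, len(sets) + 1)
        for combo in combinations(sorted(names), k)
    }
    union = set().union(*(s.members for s in sets))
    membership = {s.source_name: s.members for s in sets}
    for el in union:
        combo = tuple(sorted(n for n in names if el in membership[n]))
        region_counts[combo] += 1
    return VennResult(common, region_counts, {n: len(membership[n]) for n in names})


def _validate_seq(seq: str, allowed: str, what: str) -> None:
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in allowed:
            raise ValueError(f"invalid character {ch!r} at position {i + 1} of {what}")


def reverse_complement(seq: str, alphabet: str = "DNA") -> str:
    """Reverse complement of a DNA or RNA string (case-insensitive input,
    uppercase output in the requested alphabet)."""
    if alphabet not in ("DNA", "RNA"):
        raise ValueError(f"alphabet must be DNA or RNA, got {alphabet!r}")
    _validate_seq(seq, "ACGTU", "sequence")
    up = seq.upper().replace("U" if alphabet == "DNA" else "T", "T" if alphabet == "DNA" else "U")
    table = _DNA_COMPLEMENT if alphabet == "DNA" else _RNA_COMPLEMENT
    return up.translate(table)[::-1]


@dataclass(frozen=True)
class SeedMatchSite:
    """One seed-match site on a UTR: 1-based inclusive coordinates."""

    utr_position_start: int
    utr_position_end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        length = self.utr_position_end - self.utr_position_start + 1
        if length != SITE_LENGTH[self.site_type]:
            raise ValueError(
                f"{self.site_type} site must span {SITE_LENGTH[self.site_type]} nt, got {length}"
            )


def find_seed_matches(mirna_seq: str, utr_seq: str) -> list[SeedMatchSite]:
    """Scan a UTR (5'->3') for canonical seed sites of one miRNA (5'->3').

    The UTR may be DNA or RNA (U/T equivalent, case-insensitive) and may
    contain N (never matches).  Overlapping loci are all reported; at a
    single seed-hexamer locus only the longest applicable site type is
    kept.
    """
    _validate_seq(mirna_seq, "ACGU" + "T", "miRNA")
    if len(mirna_seq) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    _validate_seq(utr_seq, "ACGTUN", "UTR")
    mir = mirna_seq.upper().replace("T", "U")
    utr = utr_seq.upper().replace("T", "U")

    site7 = reverse_complement(mir[1:8], alphabet="RNA")  # rc of m2..m8
    hex6 = site7[1:]                                      # rc of m2..m7
    m8_base = site7[0]

    sites: list[SeedMatchSite] = []
    start = utr.find(hex6)
    while start != -1:
        has_m8 = start > 0 and utr[start - 1] == m8_base
        has_a1 = start + 6 < len(utr) and utr[start + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedMatchSite(start, start + 7, "8mer"))
        elif has_m8:
            sites.append(SeedMatchSite(start, start + 6, "7mer-m8"))
        elif has_a1:
            sites.append(SeedMatchSite(start + 1, start + 7, "7mer-A1"))
        else:
            sites.append(SeedMatchSite(start + 1, start + 6, "6mer"))
        start = utr.find(hex6, start + 1)
    return sites


def sites_to_frame(sites: Sequence[SeedMatchSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "utr_position_start": s.utr_position_start,
                "utr_position_end": s.utr_position_end,
                "site_type": s.site_type,
            }
            for s in sites
        ],
        columns=["utr_position_start", "utr_position_end", "site_type"],
    )
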