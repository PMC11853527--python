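"""Somatic-mutation merging, classification, 7-residue-window hotspot
profiles and region statistics for a protein-level mutation screen.

Records are protein-level changes (1-based residue position, reference and
alternate amino acid).  Merging keeps the primary database in full —
recurrent entries are separate mutation events — and admits a secondary
record only when its (position, ref, alt) key is new.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "WindowProfile",
    "RegionStats",
    "merge_databases",
    "classify",
    "window_scan",
    "region_statistics",
    "flag_hotspots",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MutationRecord:
    position: int
    ref_aa: str
    alt_aa: str          # one-letter AA, "*" (stop) or "=" (silent)
    source_db: str = ""
    tissue: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if self.ref_aa not in VALID_AA:
            raise ValueError(f"invalid reference amino acid {self.ref_aa!r}")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_aa, self.alt_aa)


@dataclass
class WindowProfile:
    counts: np.ndarray       # windowed per-residue counts, length L
    raw_counts: np.ndarray   # unwindowed per-residue counts
    window: int


@dataclass
class RegionStats:
    region: tuple[str, int, int]
    affected_fraction: float    # percent of residues with >= 1 mutation
    mutations_per_residue: float


def classify(record: MutationRecord) -> str:
    """missense | silent | stop."""
    alt = record.alt_aa
    if alt == "*":
        return "stop"
    if alt == "=" or alt == record.ref_aa:
        return "silent"
    if alt not in VALID_AA:
        raise ValueError(f"invalid alternate amino acid {alt!r}")
    return "missense"


def merge_databases(primary: list[MutationRecord],
                    secondaries: list[list[MutationRecord]]
                    ) -> list[MutationRecord]:
    """Primary-first merge across databases.

    All primary records are kept (recurrences included).  A secondary record
    is appended only when its protein-level key is absent from the primary
    set and from previously admitted secondaries.  Conflicting reference
    amino acids at a shared position are warned about; the primary wins.
    """
    merged = list(primary)
    ref_at = {}
    for r in primary:
        ref_at.setdefault(r.position, r.ref_aa)
    seen = {r.key for r in primary}
    for secondary in secondaries:
        for r in secondary:
            known_ref = ref_at.get(r.position)
            if known_ref is not None and known_ref != r.ref_aa:
                log.warning("conflicting ref at position %d: %s (primary) vs "
                            "%s (%s); primary wins", r.position, known_ref,
                            r.ref_aa, r.source_db)
                continue
            if r.key in seen:
                continue
            seen.add(r.key)
            ref_at.setdefault(r.position, r.ref_aa)
            merged.append(r)
    return merged


def window_scan(records: list[MutationRecord], protein_length: int,
                window: int = 7,
                classes: frozenset[str] | set[str] = frozenset({"missense"}),
                ) -> WindowProfile:
    """Windowed per-residue mutation counts.

    ``counts[i]`` is the number of selected-class records within the
    centered window (i.e. +/- (window-1)/2 residues), clipped at the
    termini with no wraparound.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    raw = np.zeros(protein_length, dtype=int)
    for r in records:
        if r.position > protein_length:
            raise ValueError(f"position {r.position} beyond protein length")
        if classify(r) in classes:
            raw[r.position - 1] += 1
    counts = np.convolve(raw, np.ones(window, dtype=int), mode="same")
    return WindowProfile(counts=counts, raw_counts=raw, window=window)


def region_statistics(records: list[MutationRecord],
                      regions: list[tuple[str, int, int]]
                      ) -> list[RegionStats]:
    """Affected-residue percentage and mutation density per region.

    ``affected_fraction`` counts distinct residues with at least one record
    (any class) as a percentage of the region length;
    ``mutations_per_residue`` counts all records, recurrences included.
    """
    out = []
    for name, start, end in regions:
        if start > end or start < 1:
            raise ValueError(f"invalid region bounds for {name!r}")
        length = end - start + 1
        in_region = [r for r in records if start <= r.position <= end]
        affected = len({r.position for r in in_region})
        out.append(RegionStats(
            region=(name, start, end),
            affected_fraction=100.0 * affected / length,
            mutations_per_residue=len(in_region) / length,
        ))
    return out


def flag_hotspots(profile: WindowProfile, threshold_factor: float = 2.0,
                  ) -> list[tuple[int, int]]:
    """Candidate hotspot intervals (1-based, inclusive) where the windowed
    count is at least ``threshold_factor`` times the protein-wide mean.

    A configurable stand-in for a visual hotspot call, not a statistical
    test.
    """
    mean = profile.counts.mean()
    if mean == 0:
        return []
    above = profile.counts >= threshold_factor * mean
    intervals = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i + 1
        elif not flag and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(above)))
    return intervals
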