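"""Structural-impact classification of precursor variants.

Each position of the extended miRNA-sense window (flank + hairpin + flank)
gets a base-layer label (``flank``, ``arm``, ``loop``) plus ``mature`` and
``seed`` overlay flags from the annotation (seed = mature positions 2-8).
A variant's *impact* under a folding paradigm is the highest-ranked region
(seed > mature > loop > arm > flank) containing any position whose pairing
status or partner changed between the reference and alternative folds;
``no_change`` if the two structures agree everywhere.  Note that the
variant's own location and its impact are decoupled: a seed variant whose
only structural effect is in the flank has impact ``flank``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genomic_io import MirnaLocus
from .rna_structure import DotBracket
from .selection import VariantAssignment

__all__ = [
    "REGION_PRIORITY",
    "RegionMap",
    "ImpactCall",
    "assign_regions",
    "locate_variant",
    "build_alignment",
    "classify_impact",
]

REGION_PRIORITY = {"seed": 5, "mature": 4, "loop": 3, "arm": 2, "flank": 1}


@dataclass
class RegionMap:
    """Per-position labels over the extended miRNA-sense window."""

    base: tuple[str, ...]            # flank / arm / loop, length = window
    mature_mask: np.ndarray          # bool, 1-based positions at index-1
    seed_mask: np.ndarray
    flank: int
    locus_name: str

    def __post_init__(self) -> None:
        if len(self.base) != len(self.mature_mask) or \
                len(self.base) != len(self.seed_mask):
            raise ValueError("region layers must have equal length")
        if np.any(self.seed_mask & ~self.mature_mask):
            raise ValueError("seed positions must lie within mature positions")

    def __len__(self) -> int:
        return len(self.base)

    def label(self, sense_pos: int) -> str:
        """Effective label of a 1-based sense position (overlay-aware)."""
        idx = sense_pos - 1
        if not (0 <= idx < len(self.base)):
            raise IndexError(f"sense position {sense_pos} outside window")
        if self.seed_mask[idx]:
            return "seed"
        if self.mature_mask[idx]:
            return "mature"
        return self.base[idx]


def _hairpin_loop_span(pairs, hp_lo: int, hp_hi: int,
                       target_mid: float) -> Optional[tuple[int, int]]:
    """Innermost-pair loop of the hairpin's main stem: among pairs enclosing
    no other pair (both ends inside the hairpin), pick the one whose
    enclosed interval contains ``target_mid`` (or the closest one)."""
    inside = [(a, b) for a, b in pairs if hp_lo <= a and b <= hp_hi]
    if not inside:
        return None
    closing = []
    for a, b in inside:
        if not any(a < c and d < b for c, d in inside if (c, d) != (a, b)):
            closing.append((a, b))
    def keyfun(ab):
        a, b = ab
        contains = a < target_mid < b
        return (0 if contains else 1, abs((a + b) / 2 - target_mid))
    a, b = min(closing, key=keyfun)
    if b - a <= 1:
        return None
    return a + 1, b - 1


def assign_regions(locus: MirnaLocus, ref_structure: DotBracket,
                   flank: int) -> RegionMap:
    """Label the extended window; the loop is the unpaired stretch enclosed
    by the innermost pair of the main stem of ``ref_structure`` (fallback:
    the gap between the two mature arms when the hairpin has no pair)."""
    if not locus.matures:
        raise ValueError(f"unusable locus {locus.name}: no mature annotations")
    L = locus.hairpin_length + 2 * flank
    if len(ref_structure.sequence) != L:
        raise ValueError(
            f"ref structure length {len(ref_structure.sequence)} != window {L}"
        )
    hp_lo, hp_hi = flank + 1, flank + locus.hairpin_length  # 1-based sense

    m_ivs = sorted(locus.mature_sense_interval(m, flank) for m in locus.matures)
    if len(m_ivs) == 2:
        target_mid = (m_ivs[0][1] + m_ivs[1][0]) / 2
    else:
        target_mid = (hp_lo + hp_hi) / 2

    pairs1 = [(a + 1, b + 1) for a, b in ref_structure.pairs]
    loop_span = _hairpin_loop_span(pairs1, hp_lo, hp_hi, target_mid)
    if loop_span is None:
        if len(m_ivs) == 2 and m_ivs[0][1] + 1 <= m_ivs[1][0] - 1:
            loop_span = (m_ivs[0][1] + 1, m_ivs[1][0] - 1)
        else:
            loop_span = None

    base = []
    for pos in range(1, L + 1):
        if pos < hp_lo or pos > hp_hi:
            base.append("flank")
        elif loop_span and loop_span[0] <= pos <= loop_span[1]:
            base.append("loop")
        else:
            base.append("arm")

    mature_mask = np.zeros(L, dtype=bool)
    seed_mask = np.zeros(L, dtype=bool)
    for m in locus.matures:
        a, b = locus.mature_sense_interval(m, flank)
        mature_mask[a - 1:b] = True
        seed_mask[a:a + 7] = True  # mature positions 2-8
    return RegionMap(tuple(base), mature_mask, seed_mask, flank, locus.name)


def locate_variant(assignment: VariantAssignment, regions: RegionMap) -> str:
    """Region of the variant itself: highest-priority effective label over
    all affected sense positions (indels use the full affected span)."""
    lo, hi = assignment.sense_span
    labels = [regions.label(p) for p in range(lo, hi + 1)
              if 1 <= p <= len(regions)]
    if not labels:
        raise ValueError("variant span outside region map")
    return max(labels, key=lambda l: REGION_PRIORITY[l])


def build_alignment(n_ref: int, n_alt: int, edit_start0: int,
                    ref_block: int, alt_block: int,
                    anchor_side: str = "left") -> np.ndarray:
    """Alt-to-ref position map implied by a single known edit (0-based).

    Positions left of the edit map identically; within the edited block the
    alleles are aligned at their anchor end (``left`` for plus-strand edits,
    ``right`` for minus-strand edits, where the VCF anchor base lands at the
    right end of the sense block); surplus alt positions map to -1
    (insertions); positions right of the edit shift by the length
    difference.
    """
    if n_alt != n_ref - ref_block + alt_block:
        raise ValueError("alignment lengths inconsistent with the edit")
    amap = np.full(n_alt, -1, dtype=np.int64)
    amap[:edit_start0] = np.arange(edit_start0)
    nmatch = min(ref_block, alt_block)
    if anchor_side == "left":
        for t in range(nmatch):
            amap[edit_start0 + t] = edit_start0 + t
    else:
        for t in range(nmatch):
            amap[edit_start0 + alt_block - 1 - t] = edit_start0 + ref_block - 1 - t
    tail = n_alt - (edit_start0 + alt_block)
    amap[edit_start0 + alt_block:] = np.arange(tail) + edit_start0 + ref_block
    return amap


@dataclass
class ImpactCall:
    variant_key: str
    mirna: str
    paradigm: str                     # centroid / MFE / MEA
    variant_region: str
    impact: str                       # seed/mature/loop/arm/flank/no_change
    changed_positions: tuple[int, ...]  # 1-based ref-sense positions

    def __post_init__(self) -> None:
        if (self.impact == "no_change") != (len(self.changed_positions) == 0):
            raise ValueError("impact/no_change inconsistent with change set")


def classify_impact(ref_fold: DotBracket, alt_fold: DotBracket,
                    regions: RegionMap, alignment: np.ndarray,
                    variant_key: str = "", mirna: str = "",
                    paradigm: str = "", variant_region: str = "") -> ImpactCall:
    """Compare pairing between ref and alt folds through the alignment.

    A ref position counts as changed when its paired/unpaired status or its
    partner (mapped to ref coordinates) differs; a deleted ref position
    counts as changed when it was paired in ref; a paired *inserted* alt
    position registers a change at the nearest mapped ref position.
    """
    n_ref = len(ref_fold.sequence)
    n_alt = len(alt_fold.sequence)
    if len(alignment) != n_alt:
        raise ValueError("alignment length does not match alt structure")
    ref_part = ref_fold.partner_array()
    alt_part = alt_fold.partner_array()

    changed: set[int] = set()
    mapped_refs = set(int(r) for r in alignment if r >= 0)
    for a in range(n_alt):
        r = int(alignment[a])
        pa = int(alt_part[a])
        if r < 0:
            # inserted base: if it pairs, report at the nearest mapped ref pos
            if pa >= 0:
                r_near = _nearest_mapped(alignment, a)
                if r_near >= 0:
                    changed.add(r_near)
            continue
        pr = int(ref_part[r])
        if pa < 0:
            if pr >= 0:
                changed.add(r)
        else:
            pa_ref = int(alignment[pa])
            if pr < 0 or pa_ref != pr:
                changed.add(r)
    for r in range(n_ref):
        if r not in mapped_refs and int(ref_part[r]) >= 0:
            changed.add(r)

    changed_1 = tuple(sorted(p + 1 for p in changed))
    if changed_1:
        impact = max((regions.label(p) for p in changed_1),
                     key=lambda l: REGION_PRIORITY[l])
    else:
        impact = "no_change"
    return ImpactCall(variant_key, mirna, paradigm, variant_region,
                      impact, changed_1)


def _nearest_mapped(alignment: np.ndarray, a: int) -> int:
    for off in range(1, len(alignment)):
        for cand in (a - off, a + off):
            if 0 <= cand < len(alignment) and alignment[cand] >= 0:
                return int(alignment[cand])
    return -1
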