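"""Cohort-variant selection: intersect variants with high-confidence miRNA
loci and retain the rare ones.

A variant is *rare* when its minor allele frequency is strictly below the
threshold (default 0.01) in every consulted population source; variants
absent from a source count as rare in that source (frequency 0), which keeps
cohort-private variants.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genomic_io import FrequencyTable, GenomicVariant, MirnaLocus

log = logging.getLogger(__name__)

__all__ = [
    "VariantAssignment",
    "CohortSummary",
    "intersect_mirna_variants",
    "filter_rare",
    "summarize_cohort",
]


@dataclass
class VariantAssignment:
    """A (variant, locus) overlap with miRNA-sense coordinates.

    ``offset`` is the 1-based sense position of the variant's first affected
    base within the extended window (hairpin +/- flank); ``sense_span`` the
    closed sense interval of all affected in-window positions.
    """

    variant: GenomicVariant
    locus: MirnaLocus
    offset: int
    sense_span: tuple[int, int]
    in_hairpin: bool
    flank: int

    def __post_init__(self) -> None:
        width = self.locus.hairpin_length + 2 * self.flank
        if not (1 <= self.offset <= width):
            raise ValueError(
                f"offset {self.offset} outside window 1..{width} "
                f"({self.variant.key} on {self.locus.name})"
            )


def intersect_mirna_variants(
    variants: Iterable[GenomicVariant],
    loci: Iterable[MirnaLocus],
    flank: int = 100,
) -> list[VariantAssignment]:
    """One assignment per (variant, locus) whose affected span overlaps the
    hairpin +/- flank window.  A variant overlapping two hairpins yields two
    assignments, analyzed independently downstream."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    loci = list(loci)
    out: list[VariantAssignment] = []
    for v in variants:
        a0, a1 = v.affected_span()
        for locus in loci:
            if locus.chrom != v.chrom:
                continue
            ws, we = locus.window(flank)
            lo, hi = max(a0, ws), min(a1, we)
            if lo > hi:
                continue
            senses = [locus.genomic_to_sense(g, flank) for g in (lo, hi)]
            span = (min(senses), max(senses))
            hs, he = locus.hairpin
            in_hp = max(a0, hs) <= min(a1, he)
            out.append(VariantAssignment(v, locus, span[0], span, in_hp, flank))
    out.sort(key=lambda a: (a.variant.chrom, a.variant.pos, a.locus.name, a.variant.key))
    return out


def filter_rare(
    assignments: Sequence[VariantAssignment],
    freqs: FrequencyTable,
    maf_threshold: float = 0.01,
    sources: Optional[Sequence[str]] = None,
) -> list[VariantAssignment]:
    """Keep assignments whose variant has MAF < threshold (strict) or is
    unobserved in *every* configured source."""
    if not (0.0 < maf_threshold <= 1.0):
        raise ValueError("maf_threshold must be in (0, 1]")
    if sources is None:
        sources = freqs.sources
    else:
        unknown = set(sources) - set(freqs.sources)
        if unknown:
            raise ValueError(f"unknown frequency sources: {sorted(unknown)}")
    kept = []
    for a in assignments:
        entry = freqs.lookup(a.variant.key)
        if all(entry.get(s) is None or entry[s] < maf_threshold for s in sources):
            kept.append(a)
    return kept


@dataclass
class CohortSummary:
    n_variants: int
    by_vclass: dict[str, int] = field(default_factory=dict)
    by_zygosity: dict[str, int] = field(default_factory=dict)
    n_distinct_mirnas: int = 0
    multiplicity: dict[str, int] = field(default_factory=dict)
    n_carrier_samples: int = 0

    def __post_init__(self) -> None:
        if sum(self.by_vclass.values()) != self.n_variants:
            raise ValueError("vclass counts must sum to n_variants")
        if self.n_distinct_mirnas > max(self.n_variants, 0) and self.n_variants:
            raise ValueError("more miRNAs than variants")

    def to_dict(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "by_vclass": dict(self.by_vclass),
            "by_zygosity": dict(self.by_zygosity),
            "n_distinct_mirnas": self.n_distinct_mirnas,
            "multiplicity": dict(self.multiplicity),
            "n_carrier_samples": self.n_carrier_samples,
        }


def summarize_cohort(assignments: Sequence[VariantAssignment]) -> CohortSummary:
    """Distinct-variant counts, zygosity (hom if any carrier sample is hom),
    per-miRNA multiplicity and carrier-sample count."""
    variants: dict[str, GenomicVariant] = {}
    mult: Counter = Counter()  # distinct variants per miRNA
    seen = set()
    for a in assignments:
        variants[a.variant.key] = a.variant
        pair = (a.locus.name, a.variant.key)
        if pair not in seen:
            seen.add(pair)
            mult[a.locus.name] += 1
    vclass = Counter(v.vclass for v in variants.values())
    zyg = Counter(v.zygosity() for v in variants.values())
    carriers = set()
    for v in variants.values():
        for sample, z in v.genotypes.items():
            if z != "absent":
                carriers.add(sample)
    return CohortSummary(
        n_variants=len(variants),
        by_vclass=dict(vclass),
        by_zygosity=dict(zyg),
        n_distinct_mirnas=len(mult),
        multiplicity=dict(mult),
        n_carrier_samples=len(carriers),
    )
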