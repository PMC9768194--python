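"""Packaged six-locus fixture for the printed seed-variant examples.

SYNTHETIC reconstruction: the mature miRNA sequences, GRCh37 coordinates,
strands and variant alleles in ``data/seed_loci_grch37_synthetic.tsv``
correspond to the six publicly documented seed-region rare variants
(miR-214, miR-4423, miR-509-1, miR-518a-1, miR-5586, miR-941-3), but the
hairpin loop, the partner arm and the genomic flanks around each mature are
constructed here programmatically — the real flanking genome sequence is
not bundled.  The fixture is therefore suitable for exercising strand-aware
seed mutation and coordinate arithmetic, not for folding the true
precursors.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .genomic_io import (
    GenomicVariant, Mature, MirnaLocus, SequenceStore, reverse_complement,
)

__all__ = ["SeedLocusRecord", "seed_variant_loci"]

_LOOP_RNA = "GUUUAUAUC"  # constructed hairpin loop, 9 nt
_FLANK = 120


@dataclass
class SeedLocusRecord:
    locus: MirnaLocus
    genome: SequenceStore
    variant: GenomicVariant
    expected_ref_seed: str
    expected_alt_seed: str


def _dna(rna: str) -> str:
    return rna.replace("U", "T")


def seed_variant_loci() -> list[SeedLocusRecord]:
    """Build the six seed-variant loci with synthetic hairpin context.

    Each mature is placed as the 5p arm of a constructed stem-loop (mature +
    9-nt loop + perfect reverse complement of the mature); the surrounding
    contig carries genome-scale coordinates via the SequenceStore offset.
    """
    text = resources.files("mirvar").joinpath(
        "data/seed_loci_grch37_synthetic.tsv").read_text()
    records: list[SeedLocusRecord] = []
    for li, line in enumerate(text.splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        (name, chrom, strand, m_start, m_end, mature_rna,
         pos, ref, alt, ref_seed, alt_seed) = line.split("\t")
        m_start, m_end, pos = int(m_start), int(m_end), int(pos)
        mlen = m_end - m_start + 1
        assert mlen == len(mature_rna)

        hairpin_rna = mature_rna + _LOOP_RNA + reverse_complement(mature_rna, rna=True)
        hlen = len(hairpin_rna)
        if strand == "+":
            h_start, h_end = m_start, m_start + hlen - 1
        else:
            h_end, h_start = m_end, m_end - hlen + 1
        plus_hairpin = _dna(hairpin_rna) if strand == "+" else \
            reverse_complement(_dna(hairpin_rna))

        rng = np.random.default_rng(20_000 + li)
        bases = np.array(list("ACGT"))
        left = "".join(rng.choice(bases, _FLANK))
        right = "".join(rng.choice(bases, _FLANK))
        contig_seq = left + plus_hairpin + right
        offset = h_start - _FLANK
        genome = SequenceStore({chrom: (offset, contig_seq)})

        locus = MirnaLocus(
            name=name, chrom=chrom, strand=strand,
            hairpin=(h_start, h_end),
            matures=(Mature("5p", m_start, m_end),),
            high_confidence=True,
        )
        variant = GenomicVariant(chrom, pos, ref, alt)
        records.append(SeedLocusRecord(locus, genome, variant,
                                       ref_seed, alt_seed))
    return records
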