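"""Seed mutation and seed-complement target prediction.

A variant in the seed region is applied to the mature miRNA strand-aware:
the precursor window is edited in genomic coordinates, flipped into miRNA
sense, and the mature is re-extracted as a fixed-length window, so that
insertions 5' of a position shift downstream bases (the seed is always
re-read from positions 2-8 of the edited mature, never edited in place) and
deletions backfill from the precursor.

Targets are genes whose 3'UTR contains at least one exact 7-mer complement
of the seed (7mer-m8 core match); a match immediately followed by an ``A``
in the UTR (opposite miRNA position 1) is sub-typed ``8mer``.  An optional
``full`` mode adds the 7mer-A1 class (6-mer core + A).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .genomic_io import (
    GenomicVariant, Mature, MirnaLocus, SequenceStore,
    reverse_complement, transcribe,
)
from .impact import build_alignment

log = logging.getLogger(__name__)

__all__ = [
    "WindowEdit",
    "MatureVariantResult",
    "TargetSite",
    "UtrDatabase",
    "TargetComparison",
    "apply_variant_to_window",
    "apply_variant_to_mature",
    "find_target_sites",
    "compare_target_sets",
]


@dataclass
class WindowEdit:
    """Reference and edited miRNA-sense sequences of a genomic window plus
    the alt-to-ref position map implied by the edit."""

    ref_seq: str      # RNA, miRNA sense
    alt_seq: str      # RNA, miRNA sense
    alignment: np.ndarray
    window: tuple[int, int]          # genomic interval
    strand: str
    sense_edit_start0: int           # 0-based sense index of the edited block
    ref_block: int
    alt_block: int


def _edit_window(genome: SequenceStore, chrom: str, w0: int, w1: int,
                 strand: str, variant: GenomicVariant) -> WindowEdit:
    lr, la = len(variant.ref), len(variant.alt)
    pos = variant.pos
    if pos < w0 or pos + lr - 1 > w1:
        raise ValueError(
            f"edit {variant.key} not fully inside window {chrom}:{w0}-{w1}"
        )
    plus = genome.fetch(chrom, w0, w1, "+")
    obs = plus[pos - w0:pos - w0 + lr]
    if obs != variant.ref.upper():
        raise ValueError(
            f"reference allele mismatch at {variant.key}: genome has {obs}"
        )
    edited_plus = plus[:pos - w0] + variant.alt + plus[pos - w0 + lr:]
    if strand == "+":
        ref_sense, alt_sense = plus, edited_plus
        start0 = pos - w0
        anchor = "left"
    else:
        ref_sense = reverse_complement(plus)
        alt_sense = reverse_complement(edited_plus)
        start0 = w1 - pos - lr + 1
        anchor = "right"
    alignment = build_alignment(len(ref_sense), len(alt_sense), start0,
                                lr, la, anchor)
    return WindowEdit(
        ref_seq=transcribe(ref_sense),
        alt_seq=transcribe(alt_sense),
        alignment=alignment,
        window=(w0, w1),
        strand=strand,
        sense_edit_start0=start0,
        ref_block=lr,
        alt_block=la,
    )


def apply_variant_to_window(locus: MirnaLocus, variant: GenomicVariant,
                            genome: SequenceStore, flank: int) -> WindowEdit:
    """Edit the extended precursor window (hairpin +/- flank), clipped to
    the stored contig."""
    w0, w1 = locus.window(flank)
    c0, c1 = genome.contig_interval(locus.chrom)
    w0, w1 = max(w0, c0), min(w1, c1)
    return _edit_window(genome, locus.chrom, w0, w1, locus.strand, variant)


@dataclass
class MatureVariantResult:
    mirna: str
    variant_key: str
    strand: str
    arm: str
    ref_mature: str
    alt_mature: str

    def __post_init__(self) -> None:
        if len(self.ref_mature) < 8 or len(self.alt_mature) < 8:
            raise ValueError("mature sequences must be >= 8 nt")

    @property
    def ref_seed(self) -> str:
        return self.ref_mature[1:8]

    @property
    def alt_seed(self) -> str:
        return self.alt_mature[1:8]

    @property
    def seed_changed(self) -> bool:
        return self.ref_seed != self.alt_seed


def apply_variant_to_mature(locus: MirnaLocus, mature_arm: str,
                            variant: GenomicVariant, genome: SequenceStore,
                            pad: int = 30) -> MatureVariantResult:
    """Apply a variant to the mature miRNA of the given arm, strand-aware.

    The precursor window (hairpin +/- ``pad``) is edited and the mature is
    re-extracted as a fixed-length sense window anchored at the mature
    5' end, so insertions shift downstream bases out and deletions backfill
    from the precursor.
    """
    m = locus.mature(mature_arm)
    lr = len(variant.ref)
    a0, a1 = variant.affected_span()
    if variant.vclass == "ins":
        ok = m.start <= variant.pos and variant.pos + 1 <= m.end
    else:
        ok = max(a0, m.start) <= min(a1, m.end)
    if not ok:
        raise ValueError(
            f"variant {variant.key} does not overlap mature "
            f"{locus.name}/{mature_arm} ({m.start}-{m.end})"
        )
    we = apply_variant_to_window(locus, variant, genome, pad)
    w0, w1 = we.window
    mlen = m.end - m.start + 1
    delta = variant.length_change
    pos = variant.pos
    if locus.strand == "+":
        start0 = m.start - w0
        if m.start >= pos + lr:
            start0 += delta
        elif pos < m.start < pos + lr:
            raise ValueError(
                f"{variant.key} deletes the mature 5' end of {locus.name}"
            )
        ref_start0 = m.start - w0
    else:
        start0 = w1 - m.end
        if m.end <= pos:
            start0 += delta
        elif pos < m.end < pos + lr:
            raise ValueError(
                f"{variant.key} deletes the mature 5' end of {locus.name}"
            )
        ref_start0 = w1 - m.end
    alt_mature = we.alt_seq[start0:start0 + mlen]
    if len(alt_mature) < mlen:
        raise ValueError(
            f"deletion {variant.key} consumes past the available precursor "
            f"sequence of {locus.name}"
        )
    ref_mature = we.ref_seq[ref_start0:ref_start0 + mlen]
    return MatureVariantResult(
        mirna=locus.name,
        variant_key=variant.key,
        strand=locus.strand,
        arm=mature_arm,
        ref_mature=ref_mature,
        alt_mature=alt_mature,
    )


# ---------------------------------------------------------------------------
# Target prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSite:
    transcript: int   # index of the UTR sequence within the gene
    position: int     # 0-based start of the match in the UTR
    site_type: str    # 8mer / 7mer-m8 / 7mer-A1


class UtrDatabase:
    """gene id -> list of 3'UTR RNA sequences (gene view = all transcripts)."""

    def __init__(self, utrs: Mapping[str, Sequence[str]]):
        self._utrs = {g: [transcribe(s) for s in seqs] for g, seqs in utrs.items()}

    @classmethod
    def from_fasta(cls, path) -> "UtrDatabase":
        """FASTA with headers ``gene_id|transcript_id`` (or bare gene ids);
        T and U are both accepted."""
        from Bio import SeqIO

        from .genomic_io import _open_text

        utrs: dict[str, list[str]] = {}
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                gene = rec.id.split("|")[0]
                utrs.setdefault(gene, []).append(str(rec.seq))
        return cls(utrs)

    @property
    def genes(self) -> list[str]:
        return list(self._utrs)

    def __getitem__(self, gene: str) -> list[str]:
        return list(self._utrs[gene])

    def __len__(self) -> int:
        return len(self._utrs)


def _scan(utr: str, motif: str):
    start = 0
    while True:
        hit = utr.find(motif, start)
        if hit < 0:
            return
        yield hit
        start = hit + 1  # overlapping occurrences count separately


def find_target_sites(seed: str, utrs: UtrDatabase,
                      mode: str = "7mer_m8") -> dict[str, list[TargetSite]]:
    """Scan every UTR for seed-complement sites.

    ``mode='7mer_m8'`` (default): a site is any occurrence of the 7-nt
    reverse complement of the seed; occurrences followed by ``A`` are
    sub-typed 8mer.  ``mode='full'`` additionally counts 7mer-A1 sites
    (reverse complement of seed positions 1-6, i.e. miRNA positions 2-7,
    followed by ``A``).  A gene is a target iff it has >= 1 site.
    """
    seed = seed.upper()
    if len(seed) != 7:
        raise ValueError(f"seed must be exactly 7 nt, got {len(seed)}")
    if set(seed) - set("ACGU"):
        raise ValueError(f"seed must be RNA (ACGU): {seed}")
    if mode not in ("7mer_m8", "full"):
        raise ValueError(f"unknown site mode {mode!r}")
    core7 = reverse_complement(seed, rna=True)
    core6 = reverse_complement(seed[:6], rna=True)  # miRNA positions 2-7
    out: dict[str, list[TargetSite]] = {}
    for gene, seqs in utrs._utrs.items():
        sites: list[TargetSite] = []
        for t, utr in enumerate(seqs):
            taken = set()
            for hit in _scan(utr, core7):
                has_a = hit + 7 < len(utr) and utr[hit + 7] == "A"
                st = "8mer" if has_a else "7mer-m8"
                sites.append(TargetSite(t, hit, st))
                taken.add(hit + 1)  # position of the 6-mer core within
            if mode == "full":
                for hit in _scan(utr, core6):
                    if hit + 6 < len(utr) and utr[hit + 6] == "A" and hit not in taken:
                        # exclude hits already covered by an 8mer at hit-1
                        if not (hit >= 1 and utr[hit - 1:hit + 7] == core7 + "A"):
                            sites.append(TargetSite(t, hit, "7mer-A1"))
        if sites:
            out[gene] = sorted(sites, key=lambda s: (s.transcript, s.position))
    return out


@dataclass
class TargetComparison:
    """Ref/alt target-set algebra with truncated new-target percentage."""

    mirna: str
    ref_targets: frozenset
    alt_targets: frozenset
    panel: Optional[frozenset] = None

    @property
    def common(self) -> frozenset:
        return self.ref_targets & self.alt_targets

    @property
    def new(self) -> frozenset:
        return self.alt_targets - self.ref_targets

    @property
    def lost(self) -> frozenset:
        return self.ref_targets - self.alt_targets

    @property
    def percent_new(self) -> int:
        return _percent_new(self.new, self.alt_targets, self.mirna)

    @property
    def panel_ref(self) -> Optional[frozenset]:
        return None if self.panel is None else self.ref_targets & self.panel

    @property
    def panel_alt(self) -> Optional[frozenset]:
        return None if self.panel is None else self.alt_targets & self.panel

    @property
    def panel_common(self) -> Optional[frozenset]:
        return None if self.panel is None else self.panel_ref & self.panel_alt

    @property
    def panel_new(self) -> Optional[frozenset]:
        return None if self.panel is None else self.panel_alt - self.panel_ref

    @property
    def panel_percent_new(self) -> Optional[int]:
        if self.panel is None:
            return None
        return _percent_new(self.panel_new, self.panel_alt, self.mirna)


def _percent_new(new: frozenset, alt: frozenset, name: str) -> int:
    if not alt:
        log.warning("%s: empty alt target set; percent_new reported as 0", name)
        return 0
    return math.floor(100 * len(new) / len(alt))


def compare_target_sets(ref_targets, alt_targets, panel=None,
                        mirna: str = "") -> TargetComparison:
    """Set algebra between reference and alternative target gene sets; the
    new-target percentage is computed on the alt set size with integer
    truncation (floor), and panel-restricted versions are included when a
    candidate-gene panel is supplied."""
    return TargetComparison(
        mirna=mirna,
        ref_targets=frozenset(ref_targets),
        alt_targets=frozenset(alt_targets),
        panel=None if panel is None else frozenset(panel),
    )
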