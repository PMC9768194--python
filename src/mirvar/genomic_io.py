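"""Readers and coordinate conventions for the pipeline's genomic inputs.

Conventions used throughout the package:

* Genomic intervals are 1-based and closed (miRBase GFF3 style); conversion
  to 0-based half-open happens only at Python string/array boundaries.
* "miRNA-sense" coordinates run 5'->3' along the miRNA precursor, i.e. along
  the plus strand for a ``+`` locus and along the reverse complement for a
  ``-`` locus.
* Indel alleles are kept VCF-style (left-anchored, first base shared between
  ref and alt) but trimmed to their minimal anchored representation so that
  equivalent spellings map to the same variant key.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "reverse_complement",
    "transcribe",
    "GenomicVariant",
    "Mature",
    "MirnaLocus",
    "SequenceStore",
    "FrequencyTable",
    "normalize_alleles",
    "read_vcf",
    "read_mirna_annotation",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


_DNA_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_RNA_COMP = str.maketrans("ACGUTNacgutn", "UGCAANugcaan")


def reverse_complement(seq: str, rna: Optional[bool] = None) -> str:
    """Watson-Crick reverse complement of a DNA or RNA string.

    The alphabet is auto-detected (``U`` present -> RNA, ``T`` present ->
    DNA); for ambiguous strings ``rna`` decides (default DNA).  Unknown
    characters raise :class:`ValueError`.
    """
    allowed = set("ACGTUNacgtun")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    if rna is None:
        if "U" in seq or "u" in seq:
            rna = True
        elif "T" in seq or "t" in seq:
            rna = False
        else:
            rna = False
    table = _RNA_COMP if rna else _DNA_COMP
    return seq.translate(table)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA (T->U), uppercased."""
    return seq.upper().replace("T", "U")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim ref/alt to the minimal left-anchored representation.

    Shared trailing bases are removed first, then shared leading bases
    (advancing ``pos``), always leaving at least one base on each allele so
    indels keep their VCF anchor.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class GenomicVariant:
    """A single normalized cohort variant with per-sample zygosity.

    ``genotypes`` maps sample name to one of ``"absent"``, ``"het"``,
    ``"hom"`` (diploid calls only; ``0/0`` and missing both map to absent).
    """

    chrom: str
    pos: int  # 1-based position of the first ref base (anchor for indels)
    ref: str
    alt: str
    genotypes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for z in self.genotypes.values():
            if z not in ("absent", "het", "hom"):
                raise ValueError(f"bad zygosity {z!r}")

    @property
    def vclass(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "snv"
        return "ins" if len(self.alt) > len(self.ref) else "del"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def affected_span(self) -> tuple[int, int]:
        """Genomic closed interval of bases affected by the edit.

        SNV: the substituted base.  Deletion: the deleted bases (anchor
        excluded).  Insertion: the two bases flanking the insertion point.
        """
        if self.vclass == "snv":
            return self.pos, self.pos
        if self.vclass == "del":
            return self.pos + 1, self.pos + len(self.ref) - 1
        return self.pos, self.pos + 1

    def zygosity(self) -> str:
        """Variant-level zygosity: hom if any carrier is hom, else het/absent."""
        calls = set(self.genotypes.values())
        if "hom" in calls:
            return "hom"
        if "het" in calls:
            return "het"
        return "absent"


def read_vcf(path, sample_names: Optional[Sequence[str]] = None) -> list[GenomicVariant]:
    """Read a VCF into normalized :class:`GenomicVariant` records.

    One variant is emitted per ALT allele per site (multiallelic records are
    split).  Records without a usable GT field are retained with all
    genotypes absent and a logged warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_names is not None:
        missing = set(sample_names) - set(samples)
        if missing:
            raise ParseError(f"samples not present in VCF: {sorted(missing)}")
        keep = [samples.index(s) for s in sample_names]
    else:
        sample_names = samples
        keep = list(range(len(samples)))

    out: list[GenomicVariant] = []
    record_no = 0
    try:
        for v in vcf:
            record_no += 1
            gts = None
            if samples:
                try:
                    gts = v.genotypes  # [[a0, a1, phased], ...]
                except Exception:
                    gts = None
            if samples and gts is None:
                log.warning(
                    "record %d (%s:%d) has no usable GT field; "
                    "genotypes set to absent", record_no, v.CHROM, v.POS,
                )
            for ai, alt in enumerate(v.ALT, start=1):
                if alt is None or set(alt.upper()) - set("ACGTN"):
                    raise ParseError(
                        f"record {record_no}: unsupported ALT allele {alt!r}"
                    )
                pos, ref, nalt = normalize_alleles(v.POS, v.REF, alt)
                genos: dict[str, str] = {}
                for name, si in zip(sample_names, keep):
                    if gts is None:
                        genos[name] = "absent"
                        continue
                    alleles = [a for a in gts[si][:-1] if a is not None]
                    n = sum(1 for a in alleles if a == ai)
                    genos[name] = "hom" if n == 2 else ("het" if n == 1 else "absent")
                out.append(GenomicVariant(v.CHROM, pos, ref, nalt, genos))
    except ParseError:
        raise
    except Exception as exc:  # htslib-level failures
        raise ParseError(f"malformed VCF record at record {record_no + 1}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# miRNA annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mature:
    arm: str  # "5p" or "3p"
    start: int  # 1-based genomic, closed
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p/3p, got {self.arm!r}")
        if self.end - self.start + 1 < 8:
            raise ValueError("mature must be >= 8 nt (needs a seed at positions 2-8)")


@dataclass
class MirnaLocus:
    """A miRNA hairpin with its mature products and a confidence flag."""

    name: str
    chrom: str
    strand: str
    hairpin: tuple[int, int]  # 1-based closed genomic interval
    matures: tuple[Mature, ...] = ()
    high_confidence: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        hs, he = self.hairpin
        if hs < 1 or he < hs:
            raise ValueError(f"bad hairpin interval {self.hairpin}")
        ivs = []
        for m in self.matures:
            if m.start < hs or m.end > he:
                raise ValueError(
                    f"{self.name}: mature {m.start}-{m.end} outside hairpin {self.hairpin}"
                )
            ivs.append((m.start, m.end))
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.name}: overlapping mature intervals")

    @property
    def hairpin_length(self) -> int:
        return self.hairpin[1] - self.hairpin[0] + 1

    def window(self, flank: int) -> tuple[int, int]:
        """Extended genomic interval hairpin +/- flank (may start below 1)."""
        return self.hairpin[0] - flank, self.hairpin[1] + flank

    def genomic_to_sense(self, g: int, flank: int = 0) -> int:
        """Map a genomic position into 1-based miRNA-sense coordinates over
        the extended window (hairpin +/- flank)."""
        ws, we = self.window(flank)
        if self.strand == "+":
            return g - ws + 1
        return we - g + 1

    def mature_sense_interval(self, m: Mature, flank: int = 0) -> tuple[int, int]:
        a = self.genomic_to_sense(m.start, flank)
        b = self.genomic_to_sense(m.end, flank)
        return (a, b) if a <= b else (b, a)

    def mature(self, arm: str) -> Mature:
        for m in self.matures:
            if m.arm == arm:
                return m
        raise KeyError(f"{self.name} has no {arm} mature")


def _infer_arm(name: str, hairpin_mid: float, start: int, end: int, strand: str) -> str:
    low = name.lower()
    if low.endswith("5p") or "-5p" in low:
        return "5p"
    if low.endswith("3p") or "-3p" in low:
        return "3p"
    mid = (start + end) / 2
    if strand == "+":
        return "5p" if mid < hairpin_mid else "3p"
    return "5p" if mid > hairpin_mid else "3p"


def read_mirna_annotation(
    path,
    confidence_key: str = "confidence",
    confidence_value: str = "high",
) -> list[MirnaLocus]:
    """Read a miRBase-dialect GFF3 into :class:`MirnaLocus` records.

    Hairpins are ``miRNA_primary_transcript`` features; matures are ``miRNA``
    features pointing at their hairpin via ``Derives_from``.  The confidence
    flag is read from the attribute ``confidence_key`` (default
    ``confidence=high``).  Matures without a resolvable parent are skipped
    with a warning; hairpins without matures are retained (unusable for seed
    analysis but still foldable).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    hairpins: dict[str, dict] = {}
    for f in db.features_of_type("miRNA_primary_transcript"):
        name = f.attributes.get("Name", [f.id])[0]
        conf = f.attributes.get(confidence_key, [None])[0]
        hairpins[f.id] = {
            "name": name,
            "chrom": f.seqid,
            "strand": f.strand,
            "interval": (f.start, f.end),
            "high_confidence": conf == confidence_value,
            "matures": [],
        }
    for f in db.features_of_type("miRNA"):
        parent = f.attributes.get("Derives_from", [None])[0]
        if parent is None or parent not in hairpins:
            log.warning("mature %s has no parent hairpin; skipped", f.id)
            continue
        h = hairpins[parent]
        mname = f.attributes.get("Name", [f.id])[0]
        mid = sum(h["interval"]) / 2
        arm = _infer_arm(mname, mid, f.start, f.end, h["strand"])
        h["matures"].append(Mature(arm, f.start, f.end))

    loci = []
    for h in hairpins.values():
        locus = MirnaLocus(
            name=h["name"],
            chrom=h["chrom"],
            strand=h["strand"],
            hairpin=h["interval"],
            matures=tuple(sorted(h["matures"], key=lambda m: m.start)),
            high_confidence=h["high_confidence"],
        )
        if not locus.matures:
            log.warning("hairpin %s has no mature annotations; unusable for "
                        "seed analysis", locus.name)
        loci.append(locus)
    loci.sort(key=lambda l: (l.chrom, l.hairpin[0], l.name))
    return loci


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

class SequenceStore:
    """Uppercase DNA per contig with strand-aware closed-interval fetch.

    Contigs may be stored with a coordinate ``offset`` so that a short FASTA
    excerpt can carry genome-scale coordinates: a record whose description
    contains ``offset=N`` places its first base at genomic position ``N``
    (1-based).
    """

    def __init__(self, contigs: Mapping[str, str] | Mapping[str, tuple[int, str]]):
        self._store: dict[str, tuple[int, str]] = {}
        for name, val in contigs.items():
            if isinstance(val, tuple):
                offset, seq = val
            else:
                offset, seq = 1, val
            self._store[name] = (int(offset), seq.upper())

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        from Bio import SeqIO

        contigs: dict[str, tuple[int, str]] = {}
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                offset = 1
                for tok in rec.description.split():
                    if tok.startswith("offset="):
                        offset = int(tok.split("=", 1)[1])
                contigs[rec.id] = (offset, str(rec.seq))
        if not contigs:
            raise ParseError(f"no FASTA records in {path}")
        return cls(contigs)

    @property
    def contigs(self) -> list[str]:
        return list(self._store)

    def contig_interval(self, chrom: str) -> tuple[int, int]:
        offset, seq = self._store[chrom]
        return offset, offset + len(seq) - 1

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence of the 1-based closed interval, reverse-complemented
        when ``strand`` is ``-``."""
        if chrom not in self._store:
            raise KeyError(f"unknown contig {chrom!r}")
        offset, seq = self._store[chrom]
        if start > end:
            raise ValueError(f"start > end ({start} > {end})")
        i0 = start - offset
        i1 = end - offset + 1
        if i0 < 0 or i1 > len(seq):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside stored sequence "
                f"({chrom}:{offset}-{offset + len(seq) - 1})"
            )
        sub = seq[i0:i1]
        return reverse_complement(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# Population allele frequencies
# ---------------------------------------------------------------------------

class FrequencyTable:
    """Variant key -> {source -> MAF}; a missing key means the variant was
    not observed in that source."""

    def __init__(self, table: Mapping[str, Mapping[str, float]], sources: Sequence[str]):
        self._table = {k: dict(v) for k, v in table.items()}
        self._sources = list(sources)
        for k, srcs in self._table.items():
            for s, maf in srcs.items():
                if s not in self._sources:
                    raise ValueError(f"unknown source {s!r} for {k}")
                if not (0.0 <= maf <= 1.0):
                    raise ValueError(f"MAF out of [0,1] for {k}/{s}: {maf}")

    @classmethod
    def from_tsv(cls, path) -> "FrequencyTable":
        """TSV with header ``chrom pos ref alt <source1> <source2> ...``;
        empty cells mean not observed in that source."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = ["chrom", "pos", "ref", "alt"]
        if list(df.columns[:4]) != required:
            raise ParseError(
                f"frequency TSV must start with columns {required}, "
                f"got {list(df.columns[:4])}"
            )
        sources = list(df.columns[4:])
        if len(sources) < 2:
            raise ParseError("frequency table needs at least two sources")
        table: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            pos, ref, alt = normalize_alleles(int(row.pos), str(row.ref), str(row.alt))
            key = f"{row.chrom}:{pos}:{ref}>{alt}"
            entry = {}
            for s in sources:
                val = getattr(row, s)
                if pd.notna(val):
                    entry[s] = float(val)
            table[key] = entry
        return cls(table, sources)

    @property
    def sources(self) -> list[str]:
        return list(self._sources)

    def lookup(self, key: str) -> dict[str, float]:
        return dict(self._table.get(key, {}))

    def __contains__(self, key: str) -> bool:
        return key in self._table
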