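"""Seeded synthetic dataset with planted ground truth.

Generates a toy genome carrying stem-loop miRNA genes on both strands, a
cohort VCF with variants planted in designed precursor regions (flank, arm,
loop, mature, seed) at designed rarity and zygosity, a 3'UTR database with
planted seed-complement sites for a designated reference/alternative seed
pair, a GO-style gene-set annotation with one planted enriched term, and a
candidate-gene panel.  Every planted fact is recorded in a
:class:`SyntheticTruth` so downstream stages can be checked exactly.

The default configuration mirrors the cohort this pipeline is built for:
100 samples, 86 rare variants in miRNA windows (six of them in seed
regions, six homozygous, 82 SNVs + 2 insertions + 2 deletions), a MAF-0.01
rarity design over two population sources, and UTR gene groups of 40
(ref-only) / 60 (both) / 100 (alt-only) planted target genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .genomic_io import (
    GenomicVariant, Mature, MirnaLocus, SequenceStore,
    reverse_complement, transcribe,
)
from .rna_structure import nussinov_fold

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_mirna_genome",
    "generate_cohort_vcf",
    "generate_utr_and_annotation",
    "generate_dataset",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int                                   # mandatory rng seed
    n_samples: int = 100
    n_mirnas: int = 80
    n_low_confidence: int = 8                   # loci without the confidence flag
    arm_len: int = 25
    loop_len: int = 9
    mature_len: int = 22
    mismatch_rate: float = 0.05
    flank: int = 100
    rare_region_counts: dict = field(default_factory=lambda: {
        "flank": 9, "arm": 32, "loop": 7, "mature": 32, "seed": 6})
    n_rare_hom: int = 6
    n_ins: int = 2                              # planted within the rare set
    n_del: int = 2
    n_common: int = 20                          # MAF >= threshold variants
    n_decoy: int = 30                           # outside miRNA windows
    maf_threshold: float = 0.01
    sources: tuple = ("thousand_genomes", "gnomad")
    # 3'UTR / enrichment design
    n_ref_only: int = 40
    n_both: int = 60
    n_alt_only: int = 100
    n_background: int = 200
    utr_len_range: tuple = (500, 1500)
    sites_per_gene: tuple = (1, 3)
    n_terms: int = 30
    term_size_range: tuple = (10, 40)
    planted_term_id: str = "T_NSD"
    planted_term_name: str = "nervous system development"
    panel_size: int = 80

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a random seed is mandatory")
        if any(v < 0 for v in self.rare_region_counts.values()):
            raise ValueError("region counts must be >= 0")
        if not (0 <= self.mismatch_rate < 0.5):
            raise ValueError("mismatch_rate must be in [0, 0.5)")


@dataclass
class PlantedVariant:
    key: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    locus: Optional[str]          # None for decoys
    region: Optional[str]         # designed region class
    rare: bool
    in_mirna_window: bool
    high_confidence_locus: bool
    zygosity: str                 # designed variant-level zygosity
    carriers: dict                # sample -> het/hom
    maf: dict                     # source -> value (missing = absent)
    # for seed variants: the designed mature/seed strings
    arm: Optional[str] = None
    ref_seed: Optional[str] = None
    alt_seed: Optional[str] = None


@dataclass
class SyntheticTruth:
    config_seed: int
    mirnas: dict = field(default_factory=dict)
    variants: list = field(default_factory=list)
    utr_groups: dict = field(default_factory=dict)
    planted_sites: dict = field(default_factory=dict)
    planted_term: Optional[str] = None
    expected_gained_terms: list = field(default_factory=list)
    panel: list = field(default_factory=list)

    def rare_in_mirna_keys(self) -> set[str]:
        return {v.key for v in self.variants
                if v.rare and v.in_mirna_window and v.high_confidence_locus}

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _make_hairpin(cfg: SyntheticConfig, rng) -> str:
    """Stem-loop DNA (sense orientation): arm + loop + near-complement arm."""
    for _ in range(30):
        left = _random_seq(rng, cfg.arm_len, gc=0.55)
        right = list(reverse_complement(left))
        for i in range(len(right)):
            if rng.random() < cfg.mismatch_rate:
                choices = [b for b in "ACGT" if b != right[i]]
                right[i] = choices[rng.integers(0, 3)]
        loop = _random_seq(rng, cfg.loop_len, gc=0.2)
        hp = left + loop + "".join(right)
        fold = nussinov_fold(transcribe(hp))
        if len(fold.pairs) >= int(0.7 * cfg.arm_len):
            return hp
    raise RuntimeError("failed to generate a well-folding hairpin")


def generate_mirna_genome(cfg: SyntheticConfig, rng):
    """Build the toy genome and miRNA annotation.

    Returns ``(genome, loci, truth)`` where ``truth.mirnas`` records each
    hairpin's designed sense sequence and region spans (hairpin-sense
    coordinates, 1-based).
    """
    gap = 2 * cfg.flank + 160
    hlen = 2 * cfg.arm_len + cfg.loop_len
    chrom = "chr_sim"
    parts: list[str] = []
    loci: list[MirnaLocus] = []
    truth = SyntheticTruth(config_seed=cfg.seed)
    cursor = 1
    low_conf = set(rng.choice(cfg.n_mirnas, size=cfg.n_low_confidence,
                              replace=False).tolist())
    decoy_spots: list[int] = []
    for i in range(cfg.n_mirnas):
        spacer = _random_seq(rng, gap)
        decoy_spots.append(cursor + gap // 2)
        parts.append(spacer)
        cursor += gap
        hairpin_sense = _make_hairpin(cfg, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        plus = hairpin_sense if strand == "+" else reverse_complement(hairpin_sense)
        h_start, h_end = cursor, cursor + hlen - 1
        parts.append(plus)
        cursor += hlen

        # matures: 5p at hairpin-sense 2..(1+mature_len); 3p mirrored
        m5_s, m5_e = 2, 1 + cfg.mature_len
        m3_s, m3_e = hlen - cfg.mature_len - 1, hlen - 2
        def to_genomic(s, e):
            if strand == "+":
                return h_start + s - 1, h_start + e - 1
            return h_end - e + 1, h_end - s + 1
        g5, g3 = to_genomic(m5_s, m5_e), to_genomic(m3_s, m3_e)
        name = f"sim-mir-{i + 1}"
        locus = MirnaLocus(
            name=name, chrom=chrom, strand=strand, hairpin=(h_start, h_end),
            matures=tuple(sorted(
                (Mature("5p", *g5), Mature("3p", *g3)),
                key=lambda m: m.start)),
            high_confidence=i not in low_conf,
        )
        loci.append(locus)
        truth.mirnas[name] = {
            "strand": strand,
            "hairpin": [h_start, h_end],
            "hairpin_sense_seq": hairpin_sense,
            "mature_sense": {"5p": [m5_s, m5_e], "3p": [m3_s, m3_e]},
            "seed_sense": {"5p": [m5_s + 1, m5_s + 7],
                           "3p": [m3_s + 1, m3_s + 7]},
            "loop_sense": [cfg.arm_len + 1, cfg.arm_len + cfg.loop_len],
            "high_confidence": i not in low_conf,
        }
    parts.append(_random_seq(rng, gap))
    decoy_spots.append(cursor + gap // 2)
    genome = SequenceStore({chrom: "".join(parts)})
    truth.mirnas["_decoy_spots"] = decoy_spots
    return genome, loci, truth


def write_genome_fasta(genome: SequenceStore, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.contigs:
            offset, end = genome.contig_interval(chrom)
            seq = genome.fetch(chrom, offset, end)
            header = f">{chrom}" + (f" offset={offset}" if offset != 1 else "")
            fh.write(header + "\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_gff3(loci, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for idx, locus in enumerate(loci, 1):
            hid = f"MI_{idx:04d}"
            attrs = f"ID={hid};Name={locus.name}"
            if locus.high_confidence:
                attrs += ";confidence=high"
            fh.write("\t".join([
                locus.chrom, "mirvar_sim", "miRNA_primary_transcript",
                str(locus.hairpin[0]), str(locus.hairpin[1]),
                ".", locus.strand, ".", attrs]) + "\n")
            for j, m in enumerate(locus.matures, 1):
                mid = f"{hid}_mat{j}"
                mattrs = (f"ID={mid};Name={locus.name}-{m.arm};"
                          f"Derives_from={hid}")
                fh.write("\t".join([
                    locus.chrom, "mirvar_sim", "miRNA",
                    str(m.start), str(m.end), ".", locus.strand, ".",
                    mattrs]) + "\n")


# ---------------------------------------------------------------------------
# Cohort VCF
# ---------------------------------------------------------------------------

def _sense_to_genomic(locus: MirnaLocus, sense: int) -> int:
    """Hairpin-sense position (1-based within hairpin) -> genomic."""
    if locus.strand == "+":
        return locus.hairpin[0] + sense - 1
    return locus.hairpin[1] - sense + 1


def _plus_base(genome, chrom, g) -> str:
    return genome.fetch(chrom, g, g)


def _region_positions(cfg: SyntheticConfig, info: dict, region: str,
                      rng) -> int:
    """Pick a designed hairpin-sense (or window-sense for flank) position."""
    hlen = 2 * cfg.arm_len + cfg.loop_len
    if region == "seed":
        arm = "5p" if rng.random() < 0.5 else "3p"
        a, b = info["seed_sense"][arm]
        return int(rng.integers(a, b + 1)), arm
    if region == "mature":
        arm = "5p" if rng.random() < 0.5 else "3p"
        a, b = info["mature_sense"][arm]
        sa, sb = info["seed_sense"][arm]
        cands = [p for p in range(a, b + 1) if not (sa <= p <= sb)]
        # keep away from the mature 5' end so indel spans stay in-mature
        cands = [p for p in cands if a + 2 <= p <= b - 3]
        return int(rng.choice(cands)), arm
    if region == "loop":
        a, b = info["loop_sense"]
        return int(rng.integers(a + 2, b - 1)), None
    if region == "arm":
        m5 = info["mature_sense"]["5p"]
        m3 = info["mature_sense"]["3p"]
        cands = [p for p in range(1, hlen + 1)
                 if not (m5[0] <= p <= m5[1]) and not (m3[0] <= p <= m3[1])
                 and not (info["loop_sense"][0] <= p <= info["loop_sense"][1])]
        return int(rng.choice(cands)), None
    raise ValueError(region)


def generate_cohort_vcf(cfg: SyntheticConfig, genome: SequenceStore,
                        loci, truth: SyntheticTruth, rng):
    """Plant variants with designed region classes, rarity and zygosity.

    Returns ``(vcf_text, freq_rows)``; planted facts appended to ``truth``.
    """
    from .impact import assign_regions, locate_variant
    from .rna_structure import EnergyModel, mfe_fold
    from .selection import intersect_mirna_variants

    chrom = loci[0].chrom
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    hc_loci = [l for l in loci if l.high_confidence]
    lc_loci = [l for l in loci if not l.high_confidence]
    used_pos: set[int] = set()
    planted: list[PlantedVariant] = []

    # Region classes are defined relative to the folded reference window
    # (the loop is read off the predicted structure), so planted positions
    # are validated against the reference MFE fold and re-drawn when the
    # structural label disagrees with the designed class.
    model = EnergyModel.default()
    region_cache: dict[str, object] = {}

    def located_region(locus, v) -> Optional[str]:
        if locus.name not in region_cache:
            seq = transcribe(genome.fetch(locus.chrom,
                                          *locus.window(cfg.flank),
                                          locus.strand))
            region_cache[locus.name] = assign_regions(
                locus, mfe_fold(seq, model), cfg.flank)
        assigns = intersect_mirna_variants([v], [locus], cfg.flank)
        if not assigns:
            return None
        return locate_variant(assigns[0], region_cache[locus.name])

    n_rare = sum(cfg.rare_region_counts.values())
    hom_quota = cfg.n_rare_hom
    ins_quota, del_quota = cfg.n_ins, cfg.n_del

    def pick_carriers(zyg: str) -> dict:
        n_car = int(rng.integers(1, 4))
        chosen = rng.choice(cfg.n_samples, size=n_car, replace=False)
        carriers = {samples[int(c)]: "het" for c in chosen}
        if zyg == "hom":
            carriers[samples[int(chosen[0])]] = "hom"
        return carriers

    def rare_maf() -> dict:
        r = rng.random()
        if r < 0.5:
            return {}
        out = {}
        for s in cfg.sources:
            if rng.random() < 0.7:
                out[s] = round(float(rng.uniform(0.0002,
                                                 cfg.maf_threshold * 0.9)), 6)
        return out

    # --- rare variants in high-confidence miRNA windows
    region_list = [r for r, c in sorted(cfg.rare_region_counts.items())
                   for _ in range(c)]
    rng.shuffle(region_list)
    indel_regions = {"mature": ins_quota, "arm": del_quota}
    for ridx, region in enumerate(region_list):
        for _ in range(200):
            locus = hc_loci[int(rng.integers(0, len(hc_loci)))]
            info = truth.mirnas[locus.name]
            if region == "flank":
                off = int(rng.integers(8, cfg.flank - 8))
                side = rng.random() < 0.5
                if locus.strand == "+":
                    g = locus.hairpin[0] - off if side else locus.hairpin[1] + off
                else:
                    g = locus.hairpin[1] + off if side else locus.hairpin[0] - off
                arm = None
            else:
                sense, arm = _region_positions(cfg, info, region, rng)
                g = _sense_to_genomic(locus, sense)
            if g in used_pos or (g - 1) in used_pos or (g + 1) in used_pos \
                    or (g + 2) in used_pos:
                continue
            vclass = "snv"
            if region == "mature" and indel_regions["mature"] > 0:
                vclass = "ins"
            elif region == "arm" and indel_regions["arm"] > 0:
                vclass = "del"
            ref_b = _plus_base(genome, chrom, g)
            if vclass == "snv":
                alt_allele = str(rng.choice([b for b in "ACGT" if b != ref_b]))
                ref_allele = ref_b
            elif vclass == "ins":
                ref_allele = ref_b
                alt_allele = ref_b + "".join(rng.choice(_BASES, 2))
            else:  # del: anchor + 2 deleted bases
                ref_allele = genome.fetch(chrom, g, g + 2)
                alt_allele = ref_b
            v = GenomicVariant(chrom, g, ref_allele, alt_allele)
            if v.vclass != vclass:
                continue  # e.g. alt insert equal to ref suffix; retry
            if located_region(locus, v) != region:
                continue
            zyg = "hom" if hom_quota > 0 else "het"
            if zyg == "hom":
                hom_quota -= 1
            carriers = pick_carriers(zyg)
            pv = PlantedVariant(
                key=v.key, chrom=chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                vclass=vclass, locus=locus.name, region=region, rare=True,
                in_mirna_window=True, high_confidence_locus=True,
                zygosity=zyg, carriers=carriers, maf=rare_maf(),
            )
            if region == "seed" and vclass == "snv":
                ms, me = info["mature_sense"][arm]
                mature_rna = transcribe(
                    info["hairpin_sense_seq"][ms - 1:me])
                mp = sense - ms  # 0-based position within mature
                sense_ref = mature_rna[mp]
                sense_alt = transcribe(
                    _COMP[v.alt] if locus.strand == "-" else v.alt)
                alt_mature = mature_rna[:mp] + sense_alt + mature_rna[mp + 1:]
                pv.arm = arm
                pv.ref_seed = mature_rna[1:8]
                pv.alt_seed = alt_mature[1:8]
            for p in range(g - 1, g + len(ref_allele) + 1):
                used_pos.add(p)
            planted.append(pv)
            if vclass == "ins":
                indel_regions["mature"] -= 1
            elif vclass == "del":
                indel_regions["arm"] -= 1
            break
        else:
            raise RuntimeError(f"could not place a {region} variant")

    # --- common variants inside miRNA windows (+ a couple on low-conf loci)
    for i in range(cfg.n_common):
        for _ in range(200):
            pool = lc_loci if (lc_loci and i < 3) else hc_loci
            locus = pool[int(rng.integers(0, len(pool)))]
            info = truth.mirnas[locus.name]
            region = ["arm", "mature", "loop"][int(rng.integers(0, 3))]
            sense, arm = _region_positions(cfg, info, region, rng)
            g = _sense_to_genomic(locus, sense)
            if g in used_pos or g - 1 in used_pos or g + 1 in used_pos:
                continue
            ref_b = _plus_base(genome, chrom, g)
            alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
            v = GenomicVariant(chrom, g, ref_b, alt_b)
            maf = {s: round(float(rng.uniform(cfg.maf_threshold, 0.2)), 6)
                   for s in cfg.sources}
            if rng.random() < 0.3:  # rare in one source is still not rare
                src = cfg.sources[int(rng.integers(0, len(cfg.sources)))]
                maf[src] = round(float(rng.uniform(0.0002,
                                                   cfg.maf_threshold * 0.9)), 6)
            planted.append(PlantedVariant(
                key=v.key, chrom=chrom, pos=g, ref=ref_b, alt=alt_b,
                vclass="snv", locus=locus.name, region=region, rare=False,
                in_mirna_window=True,
                high_confidence_locus=locus.high_confidence,
                zygosity="het", carriers=pick_carriers("het"), maf=maf,
            ))
            used_pos.add(g)
            break
        else:
            raise RuntimeError("could not place a common variant")

    # --- decoys outside every miRNA window
    spots = truth.mirnas["_decoy_spots"]
    for i in range(cfg.n_decoy):
        for _ in range(200):
            base_spot = spots[int(rng.integers(0, len(spots)))]
            g = base_spot + int(rng.integers(-15, 16))
            if g in used_pos:
                continue
            ref_b = _plus_base(genome, chrom, g)
            alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
            v = GenomicVariant(chrom, g, ref_b, alt_b)
            maf = {} if rng.random() < 0.5 else \
                {s: round(float(rng.uniform(0.0002, 0.3)), 6)
                 for s in cfg.sources}
            planted.append(PlantedVariant(
                key=v.key, chrom=chrom, pos=g, ref=ref_b, alt=alt_b,
                vclass="snv", locus=None, region=None,
                rare=all(m < cfg.maf_threshold for m in maf.values()),
                in_mirna_window=False, high_confidence_locus=False,
                zygosity="het", carriers=pick_carriers("het"), maf=maf,
            ))
            used_pos.add(g)
            break
        else:
            raise RuntimeError("could not place a decoy variant")

    planted.sort(key=lambda p: p.pos)
    truth.variants.extend(planted)

    # --- VCF text
    offset, cend = genome.contig_interval(chrom)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={cend}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    gt_code = {"het": "0/1", "hom": "1/1"}
    for p in planted:
        gts = []
        for s in samples:
            gts.append(gt_code.get(p.carriers.get(s, ""), "0/0"))
        lines.append("\t".join([
            p.chrom, str(p.pos), ".", p.ref, p.alt, ".", "PASS", ".",
            "GT"] + gts))
    vcf_text = "\n".join(lines) + "\n"

    freq_rows = []
    for p in planted:
        if p.maf:
            row = {"chrom": p.chrom, "pos": p.pos, "ref": p.ref, "alt": p.alt}
            for s in cfg.sources:
                row[s] = p.maf.get(s, "")
            freq_rows.append(row)
    return vcf_text, freq_rows


# ---------------------------------------------------------------------------
# UTRs, panel, annotation
# ---------------------------------------------------------------------------

def _plant_gene(rng, length: int, plant: dict[str, int],
                forbidden: list[str]) -> tuple[str, dict[str, list[int]]]:
    """Background sequence with exactly ``plant[motif]`` copies of each
    required motif and zero occurrences of any forbidden motif."""
    motif_len = max((len(m) for m in plant), default=8)
    for _ in range(80):
        s = list(_random_seq(rng, length))
        occupied: list[tuple[int, int]] = []
        positions: dict[str, list[int]] = {}
        ok = True
        for motif, count in plant.items():
            placed = []
            for _ in range(count):
                for _try in range(50):
                    p = int(rng.integers(0, length - motif_len - 1))
                    if all(p + len(motif) + 1 <= a or p >= b + 1
                           for a, b in occupied):
                        occupied.append((p, p + len(motif)))
                        s[p:p + len(motif)] = motif
                        placed.append(p)
                        break
                else:
                    ok = False
            positions[motif] = sorted(placed)
        if not ok:
            continue
        out = "".join(s)
        if any(sum(1 for _ in _iter_hits(out, m)) for m in forbidden):
            continue
        if all(sum(1 for _ in _iter_hits(out, m)) == c
               for m, c in plant.items()):
            return out, positions
    raise RuntimeError("rejection sampling failed while planting sites")


def _iter_hits(seq: str, motif: str):
    start = 0
    while True:
        h = seq.find(motif, start)
        if h < 0:
            return
        yield h
        start = h + 1


def generate_utr_and_annotation(cfg: SyntheticConfig, ref_seed: str,
                                alt_seed: str, rng,
                                truth: Optional[SyntheticTruth] = None):
    """Build the UTR FASTA, panel and gene-set annotation with planted
    enrichment for the designated ref/alt seed pair (RNA strings).

    Gene groups: ref-only genes carry only ref-seed sites, both-group genes
    carry sites for both seeds, alt-only genes only alt-seed sites, and
    background genes are rejection-sampled to carry neither.  One planted
    term collects alt-only genes so that it is enriched only for the
    alternative seed.
    """
    if truth is None:
        truth = SyntheticTruth(config_seed=cfg.seed)
    ref_motif = reverse_complement(ref_seed, rna=True).replace("U", "T")
    alt_motif = reverse_complement(alt_seed, rna=True).replace("U", "T")
    if ref_motif == alt_motif:
        raise ValueError("ref and alt seeds have identical complements")

    groups = (
        [("ref_only", [ref_motif], [alt_motif])] * cfg.n_ref_only
        + [("both", [ref_motif, alt_motif], [])] * cfg.n_both
        + [("alt_only", [alt_motif], [ref_motif])] * cfg.n_alt_only
        + [("background", [], [ref_motif, alt_motif])] * cfg.n_background
    )
    fasta_lines = []
    group_members: dict[str, list[str]] = {
        "ref_only": [], "both": [], "alt_only": [], "background": []}
    planted_sites: dict[str, dict] = {}
    for gi, (group, motifs, forbidden) in enumerate(groups):
        gene = f"G{gi + 1:04d}"
        group_members[group].append(gene)
        length = int(rng.integers(*cfg.utr_len_range))
        plant = {m: int(rng.integers(cfg.sites_per_gene[0],
                                     cfg.sites_per_gene[1] + 1))
                 for m in motifs}
        seq, positions = _plant_gene(rng, length, plant, forbidden)
        rec_sites = {("ref" if m == ref_motif else "alt"): pos
                     for m, pos in positions.items()}
        planted_sites[gene] = rec_sites
        fasta_lines.append(f">{gene}|T1")
        for i in range(0, len(seq), 70):
            fasta_lines.append(seq[i:i + 70])
    utr_fasta = "\n".join(fasta_lines) + "\n"

    universe = [g for gs in group_members.values() for g in gs]
    # annotation terms: random background terms + one planted gained term
    term_rows = []
    name_rows = []
    for t in range(cfg.n_terms):
        tid = f"T{t + 1:03d}"
        size = int(rng.integers(*cfg.term_size_range))
        genes = rng.choice(universe, size=size, replace=False)
        for g in sorted(genes.tolist()):
            term_rows.append((tid, g))
        name_rows.append((tid, f"background process {t + 1}"))
    n_planted = max(10, int(0.6 * cfg.n_alt_only))
    planted_genes = rng.choice(group_members["alt_only"], size=n_planted,
                               replace=False)
    for g in sorted(planted_genes.tolist()):
        term_rows.append((cfg.planted_term_id, g))
    name_rows.append((cfg.planted_term_id, cfg.planted_term_name))

    panel = sorted(
        rng.choice(group_members["alt_only"], size=min(30, cfg.n_alt_only),
                   replace=False).tolist()
        + rng.choice(group_members["both"], size=min(20, cfg.n_both),
                     replace=False).tolist()
        + rng.choice(group_members["ref_only"], size=min(10, cfg.n_ref_only),
                     replace=False).tolist()
        + rng.choice(group_members["background"],
                     size=max(0, cfg.panel_size - 60),
                     replace=False).tolist()
    )

    truth.utr_groups = {k: sorted(v) for k, v in group_members.items()}
    truth.planted_sites = planted_sites
    truth.planted_term = cfg.planted_term_id
    truth.expected_gained_terms = [cfg.planted_term_id]
    truth.panel = panel
    return utr_fasta, panel, term_rows, name_rows, truth


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SyntheticConfig, outdir) -> tuple[dict, SyntheticTruth]:
    """Generate and write the full synthetic bundle; returns (paths, truth).

    The designated seed pair for the UTR stage is taken from the first
    planted seed SNV (sorted by key) so that the end-to-end run contains a
    variant whose target rewiring and gained term are fully known.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genome, loci, truth = generate_mirna_genome(cfg, rng)
    vcf_text, freq_rows = generate_cohort_vcf(cfg, genome, loci, truth, rng)

    seed_pvs = sorted((p for p in truth.variants
                       if p.region == "seed" and p.ref_seed and p.alt_seed
                       and p.ref_seed != p.alt_seed),
                      key=lambda p: p.key)
    if not seed_pvs:
        raise RuntimeError("no planted seed variant with a seed change")
    designated = seed_pvs[0]
    utr_fasta, panel, term_rows, name_rows, truth = generate_utr_and_annotation(
        cfg, designated.ref_seed, designated.alt_seed, rng, truth)
    truth.mirnas["_designated_seed_variant"] = designated.key

    paths = {
        "genome": outdir / "genome.fa",
        "gff3": outdir / "mirnas.gff3",
        "vcf": outdir / "cohort.vcf",
        "frequencies": outdir / "frequencies.tsv",
        "utrs": outdir / "utrs.fa",
        "panel": outdir / "panel.txt",
        "term_genes": outdir / "term_genes.tsv",
        "term_names": outdir / "term_names.tsv",
        "truth": outdir / "truth.json",
    }
    write_genome_fasta(genome, paths["genome"])
    write_gff3(loci, paths["gff3"])
    paths["vcf"].write_text(vcf_text)
    with open(paths["frequencies"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(cfg.sources) + "\n")
        for row in freq_rows:
            fh.write("\t".join(str(row[c]) for c in
                               ["chrom", "pos", "ref", "alt", *cfg.sources])
                     + "\n")
    paths["utrs"].write_text(utr_fasta)
    paths["panel"].write_text("\n".join(panel) + "\n")
    with open(paths["term_genes"], "w") as fh:
        for tid, g in term_rows:
            fh.write(f"{tid}\t{g}\n")
    with open(paths["term_names"], "w") as fh:
        for tid, name in name_rows:
            fh.write(f"{tid}\t{name}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}, truth
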