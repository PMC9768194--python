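"""End-to-end orchestration: selection -> structure/impact -> targets/ORA.

``run_pipeline`` executes the three workflow steps over the configured
inputs, writing diff-able TSV/JSON reports plus a manifest (config hash,
package version, input checksums) that suffices to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .enrichment import GeneSetAnnotation, diff_terms, run_ora
from .genomic_io import (
    FrequencyTable, SequenceStore, read_mirna_annotation, read_vcf, transcribe,
)
from .impact import assign_regions, classify_impact, locate_variant
from .rna_structure import (
    EnergyModel, centroid_structure, mea_structure, mfe_fold,
    partition_function,
)
from .selection import filter_rare, intersect_mirna_variants, summarize_cohort
from .targeting import (
    UtrDatabase, apply_variant_to_mature, apply_variant_to_window,
    compare_target_sets, find_target_sites,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "validate_inputs"]

PARADIGMS = ("centroid", "MFE", "MEA")
IMPACT_ORDER = ("arm", "flank", "mature", "seed", "no_change", "loop")


@dataclass
class PipelineConfig:
    """All inputs and parameters of a pipeline run.

    Defaults reproduce the study conditions: 100-nt folding flanks,
    MAF < 0.01 rarity in every source, raw p <= 0.05 ORA significance.
    """

    vcf: str
    gff3: str
    genome_fasta: str
    frequencies: str
    utr_fasta: Optional[str] = None
    term_genes: Optional[str] = None
    term_names: Optional[str] = None
    panel: Optional[str] = None
    outdir: str = "mirvar_out"
    flank: int = 100
    maf_threshold: float = 0.01
    paradigms: tuple = PARADIGMS
    site_mode: str = "7mer_m8"
    alpha: float = 0.05
    gamma: float = 1.0
    seed: int = 0
    energy_params: Optional[str] = None
    confidence_key: str = "confidence"
    confidence_value: str = "high"
    sample_names: Optional[Sequence[str]] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paradigms"] = list(self.paradigms)
        return d


@dataclass
class ReportBundle:
    outdir: str
    cohort_summary: dict
    selection: pd.DataFrame
    impact_calls: pd.DataFrame
    impact_summary: pd.DataFrame
    seed_table: pd.DataFrame
    target_comparison: pd.DataFrame
    term_diffs: dict
    manifest: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Report-only validation of file parse-ability, contig-name consistency
    and annotation invariants."""
    checks: list[dict] = []

    def add(name, passed, message=""):
        checks.append({"check": name, "passed": bool(passed), "message": message})

    genome = loci = variants = None
    try:
        genome = SequenceStore.from_fasta(config.genome_fasta)
        add("genome_fasta_parses", True)
    except Exception as exc:
        add("genome_fasta_parses", False, str(exc))
    try:
        loci = read_mirna_annotation(config.gff3, config.confidence_key,
                                     config.confidence_value)
        add("gff3_parses", True, f"{len(loci)} loci")
    except Exception as exc:
        add("gff3_parses", False, str(exc))
    try:
        variants = read_vcf(config.vcf, config.sample_names)
        add("vcf_parses", True, f"{len(variants)} variants")
    except Exception as exc:
        add("vcf_parses", False, str(exc))
    try:
        FrequencyTable.from_tsv(config.frequencies)
        add("frequency_table_parses", True)
    except Exception as exc:
        add("frequency_table_parses", False, str(exc))

    if genome is not None and variants is not None:
        vcf_contigs = {v.chrom for v in variants}
        missing = vcf_contigs - set(genome.contigs)
        msg = ""
        if missing:
            stripped = {c.removeprefix("chr") for c in genome.contigs} | \
                       {"chr" + c for c in genome.contigs}
            fixable = missing & stripped
            msg = f"VCF contigs missing from FASTA: {sorted(missing)}"
            if fixable:
                msg += " (rename suggestion: harmonize the 'chr' prefix)"
        add("vcf_fasta_contigs_consistent", not missing, msg)
    if genome is not None and loci is not None:
        gff_contigs = {l.chrom for l in loci}
        missing = gff_contigs - set(genome.contigs)
        add("gff3_fasta_contigs_consistent", not missing,
            f"GFF3 contigs missing from FASTA: {sorted(missing)}" if missing else "")
        no_mature = [l.name for l in loci if not l.matures]
        add("all_hairpins_have_matures", not no_mature,
            f"hairpins without matures: {no_mature}" if no_mature else "")
    return checks


def _fold_paradigms(seq: str, model: EnergyModel, gamma: float,
                    paradigms) -> dict:
    folds = {}
    if "MFE" in paradigms:
        folds["MFE"] = mfe_fold(seq, model)
    if "centroid" in paradigms or "MEA" in paradigms:
        pf = partition_function(seq, model)
        if "centroid" in paradigms:
            folds["centroid"] = centroid_structure(pf)
        if "MEA" in paradigms:
            folds["MEA"] = mea_structure(pf, gamma)
    return folds


def run_pipeline(config: PipelineConfig, stages: Sequence[str] =
                 ("select", "structure", "targets", "ora")) -> ReportBundle:
    """Run the configured stages; partial outputs are flushed per stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = EnergyModel.from_yaml(config.energy_params) \
        if config.energy_params else EnergyModel.default()

    genome = SequenceStore.from_fasta(config.genome_fasta)
    all_loci = read_mirna_annotation(config.gff3, config.confidence_key,
                                     config.confidence_value)
    loci = [l for l in all_loci if l.high_confidence and l.matures]
    variants = read_vcf(config.vcf, config.sample_names)
    freqs = FrequencyTable.from_tsv(config.frequencies)
    log.info("loaded %d variants, %d/%d high-confidence miRNA loci",
             len(variants), len(loci), len(all_loci))

    # ---- stage 1: selection -------------------------------------------------
    assignments = intersect_mirna_variants(variants, loci, config.flank)
    rare = filter_rare(assignments, freqs, config.maf_threshold)
    summary = summarize_cohort(rare)
    sel_rows = [{
        "variant_key": a.variant.key,
        "mirna": a.locus.name,
        "strand": a.locus.strand,
        "offset": a.offset,
        "in_hairpin": a.in_hairpin,
        "vclass": a.variant.vclass,
        "zygosity": a.variant.zygosity(),
    } for a in rare]
    selection_df = pd.DataFrame(
        sel_rows, columns=["variant_key", "mirna", "strand", "offset",
                           "in_hairpin", "vclass", "zygosity"])
    selection_df.to_csv(outdir / "selection.tsv", sep="\t", index=False)
    summary_dict = summary.to_dict()
    summary_dict["n_assignments"] = len(rare)
    (outdir / "cohort_summary.json").write_text(
        json.dumps(summary_dict, indent=1, sort_keys=True))

    impact_df = pd.DataFrame(columns=[
        "variant_key", "mirna", "paradigm", "variant_region", "impact",
        "n_changed_positions"])
    impact_summary = pd.DataFrame()
    seed_df = pd.DataFrame(columns=[
        "mirna", "chrom", "start", "end", "vclass", "ref", "alt",
        "ref_seed", "alt_seed"])
    targets_df = pd.DataFrame()
    term_diffs: dict = {}

    if not loci or not rare:
        log.info("no high-confidence loci or no rare variants selected; "
                 "stages 2-3 skipped")
        stages = [s for s in stages if s == "select"]

    # ---- stage 2: structure / impact ---------------------------------------
    seed_assignments = []
    if "structure" in stages:
        structures_dir = outdir / "structures"
        structures_dir.mkdir(exist_ok=True)
        ref_cache: dict[str, tuple] = {}
        calls = []
        for a in rare:
            locus = a.locus
            if locus.name not in ref_cache:
                w0, w1 = locus.window(config.flank)
                c0, c1 = genome.contig_interval(locus.chrom)
                seq = transcribe(genome.fetch(locus.chrom, max(w0, c0),
                                              min(w1, c1), locus.strand))
                folds = _fold_paradigms(seq, model, config.gamma,
                                        config.paradigms)
                regions = {p: assign_regions(locus, f, config.flank)
                           for p, f in folds.items()}
                ref_cache[locus.name] = (folds, regions)
            folds, regions = ref_cache[locus.name]
            try:
                we = apply_variant_to_window(locus, a.variant, genome,
                                             config.flank)
            except ValueError as exc:
                log.warning("structure stage skipped for %s: %s",
                            a.variant.key, exc)
                continue
            alt_folds = _fold_paradigms(we.alt_seq, model, config.gamma,
                                        config.paradigms)
            mfe_region = regions.get("MFE") or next(iter(regions.values()))
            if locate_variant(a, mfe_region) == "seed":
                seed_assignments.append(a)
            for paradigm in config.paradigms:
                vr = locate_variant(a, regions[paradigm])
                call = classify_impact(
                    folds[paradigm], alt_folds[paradigm], regions[paradigm],
                    we.alignment, a.variant.key, locus.name, paradigm, vr)
                calls.append(call)
                tag = f"{locus.name}_{a.variant.key.replace(':', '_').replace('>', '-')}_{paradigm}"
                (structures_dir / f"{tag}.txt").write_text(
                    folds[paradigm].to_vienna() + "\n"
                    + alt_folds[paradigm].to_vienna() + "\n")
        impact_df = pd.DataFrame([{
            "variant_key": c.variant_key, "mirna": c.mirna,
            "paradigm": c.paradigm, "variant_region": c.variant_region,
            "impact": c.impact,
            "n_changed_positions": len(c.changed_positions),
        } for c in calls])
        impact_df.to_csv(outdir / "impact.tsv", sep="\t", index=False)
        # summary mirroring the impact-by-paradigm table
        rows = []
        for impact in IMPACT_ORDER:
            row = {"impact": impact}
            means = []
            for p in config.paradigms:
                nsub = int(((impact_df["paradigm"] == p)
                            & (impact_df["impact"] == impact)).sum())
                ntot = int((impact_df["paradigm"] == p).sum())
                row[p] = nsub
                means.append(100 * nsub / ntot if ntot else 0.0)
            row["mean_percent"] = round(sum(means) / len(means)) if means else 0
            rows.append(row)
        impact_summary = pd.DataFrame(rows)
        changed = {
            p: 100 * float((impact_df.loc[impact_df["paradigm"] == p,
                                          "impact"] != "no_change").mean())
            for p in config.paradigms
            if int((impact_df["paradigm"] == p).sum())
        }
        impact_summary.attrs["percent_changed"] = changed
        impact_summary.to_csv(outdir / "impact_summary.tsv", sep="\t",
                              index=False)
        (outdir / "impact_percent_changed.json").write_text(
            json.dumps(changed, indent=1, sort_keys=True))

    # ---- stage 3: seed targets + ORA ----------------------------------------
    if "targets" in stages and config.utr_fasta and seed_assignments:
        utrs = UtrDatabase.from_fasta(config.utr_fasta)
        panel = None
        if config.panel:
            panel = {l.strip() for l in open(config.panel)
                     if l.strip()}
        annotation = None
        if "ora" in stages and config.term_genes:
            annotation = GeneSetAnnotation.from_tsv(
                config.term_genes, config.term_names, universe=utrs.genes)
        seed_rows, target_rows = [], []
        seen = set()
        for a in seed_assignments:
            key = (a.variant.key, a.locus.name)
            if key in seen:
                continue
            seen.add(key)
            locus = a.locus
            arm = None
            for m in locus.matures:
                s0, s1 = locus.mature_sense_interval(m, config.flank)
                if s0 <= a.sense_span[1] and a.sense_span[0] <= s1:
                    arm = m.arm
                    break
            if arm is None:
                continue
            try:
                res = apply_variant_to_mature(locus, arm, a.variant, genome)
            except ValueError as exc:
                log.warning("seed stage skipped for %s: %s", a.variant.key, exc)
                continue
            v = a.variant
            disp_ref = v.ref if v.vclass == "snv" else \
                ("-" if v.vclass == "ins" else v.ref[1:])
            disp_alt = v.alt if v.vclass == "snv" else \
                (v.alt[1:] if v.vclass == "ins" else "-")
            seed_rows.append({
                "mirna": locus.name, "chrom": v.chrom,
                "start": v.pos if v.vclass == "snv" else v.pos,
                "end": v.pos + len(v.ref) - 1,
                "vclass": v.vclass, "ref": disp_ref, "alt": disp_alt,
                "ref_seed": res.ref_seed, "alt_seed": res.alt_seed,
            })
            if not res.seed_changed:
                continue
            ref_targets = set(find_target_sites(res.ref_seed, utrs,
                                                config.site_mode))
            alt_targets = set(find_target_sites(res.alt_seed, utrs,
                                                config.site_mode))
            comp = compare_target_sets(ref_targets, alt_targets, panel,
                                       mirna=locus.name)
            row = {
                "mirna": locus.name, "variant_key": v.key,
                "ref_targets": len(comp.ref_targets),
                "alt_targets": len(comp.alt_targets),
                "common": len(comp.common), "new": len(comp.new),
                "percent_new": comp.percent_new,
            }
            if panel is not None:
                row.update({
                    "panel_ref": len(comp.panel_ref),
                    "panel_alt": len(comp.panel_alt),
                    "panel_common": len(comp.panel_common),
                    "panel_new": len(comp.panel_new),
                    "panel_percent_new": comp.panel_percent_new,
                })
            target_rows.append(row)
            if annotation is not None and ref_targets and alt_targets:
                ref_res = run_ora(ref_targets, annotation, config.alpha)
                alt_res = run_ora(alt_targets, annotation, config.alpha)
                diff = diff_terms(ref_res, alt_res)
                term_diffs[f"{locus.name}:{v.key}"] = diff.to_dict()
                for tag, results in (("ref", ref_res), ("alt", alt_res)):
                    pd.DataFrame([{
                        "term_id": r.term_id, "name": r.name, "k": r.k,
                        "K": r.K, "n": r.n, "N": r.N, "p": r.p,
                        "p_bh": r.p_bh, "significant": r.significant,
                    } for r in results]).to_csv(
                        outdir / f"ora_{locus.name}_{tag}.tsv",
                        sep="\t", index=False)
        seed_df = pd.DataFrame(seed_rows, columns=list(seed_df.columns))
        targets_df = pd.DataFrame(target_rows)
        seed_df.to_csv(outdir / "seed_table.tsv", sep="\t", index=False)
        targets_df.to_csv(outdir / "target_comparison.tsv", sep="\t",
                          index=False)
        (outdir / "term_diff.json").write_text(
            json.dumps(term_diffs, indent=1, sort_keys=True))

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(p) for name, p in (
                ("vcf", config.vcf), ("gff3", config.gff3),
                ("genome_fasta", config.genome_fasta),
                ("frequencies", config.frequencies),
                ("utr_fasta", config.utr_fasta),
                ("term_genes", config.term_genes),
                ("term_names", config.term_names),
                ("panel", config.panel),
            ) if p
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))

    return ReportBundle(
        outdir=str(outdir),
        cohort_summary=summary_dict,
        selection=selection_df,
        impact_calls=impact_df,
        impact_summary=impact_summary,
        seed_table=seed_df,
        target_comparison=targets_df,
        term_diffs=term_diffs,
        manifest=manifest,
    )
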