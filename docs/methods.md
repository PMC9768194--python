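# Methods

## Scope and coordinate conventions

The package analyzes cohort variants that fall inside miRNA precursor
windows.  All genomic intervals are 1-based and closed, matching miRBase
GFF3 and the way such coordinates are usually printed; conversion to
0-based half-open indices happens only at array/string boundaries.
"miRNA-sense" coordinates run 5′→3′ along the precursor: for a minus-strand
locus every window is reverse-complemented before analysis, and sense
position 1 corresponds to the *largest* genomic coordinate of the window.
The analysis window is the annotated hairpin plus `flank` nucleotides on
each side; the default flank of 100 nt is the value functional studies of
precursor processing support, and selection and folding use the same window
so the two stages see identical context.

Indel alleles are stored VCF-style (left-anchored, ≥ 1 nt each) and trimmed
to their minimal anchored representation, so equivalent spellings collapse
to one canonical `chrom:pos:ref>alt` key.  The anchor-free display form
("−/ATC") is derived only when writing the seed-table report.  Only diploid
genotypes are interpreted (`0/1`→het, `1/1`→hom, `0/0` and missing→absent;
phased separators accepted); multiallelic records are split per ALT allele.
How the original study handled multiallelic sites or non-diploid calls is
not documented; these are this package's own choices.

## Rarity filter

A variant is rare iff, for every configured population source, its MAF is
strictly below the threshold (default 0.01) *or* the variant is absent from
that source.  Treating absence as rarity is deliberate: cohort-private
variants are by construction missing from population databases and must
not be discarded.  The filter is monotone in the threshold and commutes
with locus assignment; both properties are tested.

## Folding model

The three structure paradigms are computed from one simplified
nearest-neighbor energy decomposition.  Every base pair closes exactly one
loop:

* **hairpin loop** — tabulated initiation penalty by loop size (≥ 3
  unpaired nt), extended beyond the table by `E(m) = E(m_max) +
  slope·ln(m/m_max)` with slope ≈ 1.75·kT;
* **stack / bulge / internal loop** — stacking energies by the ordered
  pair classes (CG, GC, GU, UG, AU, UA) when the inner pair is adjacent,
  otherwise a size-dependent bulge or internal-loop penalty (no terminal
  mismatches), with each side capped at 30 unpaired nt for O(n²·k²)
  tractability;
* **multiloop** — linear model `a + b·(branches incl. closing) +
  c·unpaired` with defaults a = 3.4, b = 0.4, c = 0.4 kcal/mol;
* **exterior** — free.

GU pairs are allowed everywhere, lone pairs are allowed, pseudoknots are
not, kT = 0.616 kcal/mol (37 °C).  The parameter values
(`src/mirvar/data/energy_params.yaml`) are round-number summaries of the
usual magnitudes of nearest-neighbor parameters, *not* a published table:
the package's claims about structure are property-based (validity,
determinism, exact agreement with enumeration under its own model), never
agreement with ViennaRNA/miRVaS outputs, and published per-region impact
percentages are correspondingly not treated as reproducible targets.

**MFE** is a Zuker-style DP (`V`/`M`/`M1`/external arrays).  **Pair
probabilities** come from McCaskill inside recursions (`QB`, `QM`, `QM1`,
external prefix/suffix) plus an outside pass implemented as the exact
adjoint of the inside recursions, which keeps the multiloop outside
contribution at O(n³) without the usual special-cased derivation.  Both
use per-nucleotide rescaling anchored at the MFE energy
(`s = exp(E_MFE/(kT·n))`) so Boltzmann sums stay inside double range even
for GC-rich 300-mers; a residual overflow raises an error rather than
returning NaN.  **Centroid** takes exactly the pairs with probability
> ½ (strict, so ties at ½ are excluded and validity needs no conflict
resolution).  **MEA** maximizes `Σ 2γ·p(i,j) + Σ q(unpaired)` by a
Nussinov-style DP over the probability matrix (γ default 1).  All tie-breaks
in tracebacks are fixed-preference (prefer pairing, smallest partner;
Nussinov: prefer unpaired, then smallest partner), making every fold
byte-deterministic; exact lexicographic minimization over co-optimal
structures was considered and dropped as bookkeeping without scientific
payoff.

All four engines are validated against exhaustive enumeration of nested
structures at n ≤ 12 (energies exact, Z and pair probabilities to ~1e-15
relative) and by a 1000-sequence validity sweep at 60–260 nt.  The kernels
are numba-compiled; first use in a session costs a few seconds of JIT.

## Region maps and impact calls

Positions of the extended window carry a base label (`flank` outside the
hairpin; inside it, `loop` = the unpaired stretch enclosed by the innermost
pair of the hairpin's main stem *in the predicted reference structure*,
falling back to the inter-mature gap when the hairpin has no pair; `arm` =
the rest) plus `mature` and `seed` overlays from the annotation (seed =
mature positions 2–8, the TargetScan convention).  Because the loop is read
off the predicted structure, region maps are computed per paradigm.

A variant's own region is the highest-priority effective label over its
affected span (indels use the full span; an insertion's span is the two
flanking bases).  Its *impact* under a paradigm compares the reference and
alternative folds through the alignment implied by the edit (positions left
of the edit map identically, inserted bases map to nothing, right of the
edit shifts by the length difference; the anchor sits left in sense
coordinates for plus-strand edits and right for minus-strand edits): a
reference position changed iff its paired/unpaired status or its mapped
partner differs; a deleted position counts as changed iff it was paired; a
paired inserted base registers at the nearest mapped reference position.
Base identity alone is never a change — the comparison is purely
structural.  The impact label is the highest-priority region containing a
change, with ranking seed > mature > loop > arm > flank chosen to mirror
the functional importance of the regions (the ranking itself is a design
choice; published tables never state one).  Structures are compared over
the full flanked window; whether upstream tools restrict to the hairpin is
undocumented, and a config flag would be the place to change it.

## Seed targeting

Seed variants are applied by editing the precursor window in genomic
coordinates, flipping to miRNA sense, and re-extracting the mature as a
fixed-length window anchored at its 5′ end.  This single rule yields the
documented behaviours: insertions 5′ of a seed position shift downstream
bases through the seed (the seed is re-read from positions 2–8 of the
edited mature, never edited in place), and deletions backfill from
precursor sequence.  An edit that would delete the mature's 5′ anchor is
refused, as is a deletion running past the available precursor.

A target site is an exact UTR occurrence of the 7-nt reverse complement of
the seed (7mer-m8 core).  Sites immediately followed by `A` in the UTR
(the base opposite miRNA position 1) are sub-typed 8mer; an optional
`full` mode also counts 7mer-A1 sites (6-mer core + A).  The default mode
deliberately excludes 6mer and 7mer-A1 matches, honoring the 7-nt seed
definition; which site-type set a given TargetScan run counted is not
generally recoverable, so absolute target counts are not treated as
reproducible, while set *algebra* is: new targets are counted against the
alternative set and percentages are floor-truncated, the only rule that
reproduces all twelve documented percentages (nearest-integer rounding
fails on several).  Genes collapse over transcripts: a gene is a target if
any of its UTRs has a site.

## Over-representation analysis

The statistic is the one-sided hypergeometric upper tail (Fisher exact
enrichment) with the universe = UTR-database genes ∩ annotation; scipy's
survival function supplies the numerics (checked exactly against
combinatorial enumeration for all N ≤ 12).  Raw p ≤ 0.05 is the primary
significance rule, mirroring common ClueGO-style practice; BH-adjusted
values are reported alongside because multiple testing is otherwise
unaddressed.  Term-redundancy "fusion" is not implemented.  Term diffing
partitions significant terms into gained/lost/shared between the
reference-seed and alternative-seed queries; the headline use is detecting
a term (e.g. a nervous-system-development gene set) that is significant
only for the mutated seed.

## Synthetic data

The generator emulates the study conditions: 100 samples; 86 rare variants
planted in high-confidence miRNA windows with the documented class mix (82
SNVs, 2 insertions, 2 deletions; 6 in seed regions; 6 homozygous) and a
region distribution (9 flank / 32 arm / 7 loop / 32 mature / 6 seed)
scaled from the published per-region spread while keeping the total at 86
and the seed count exact; two population sources with designed
rare/common/absent MAFs; common and decoy variants as negatives.  Hairpins
are built stem–loop (25-nt arms at 5% mismatch, 9-nt loops, 22-nt matures
on both arms, random strands) and rejected unless Nussinov folds ≥ 70% of
the arm; because region classes are *defined* against the folded reference
structure, planted positions are additionally validated against the
reference MFE fold and re-drawn on disagreement — the generator guarantees
its truth is recoverable under the model, which is exactly what the
end-to-end tests then verify (bookkeeping, strand handling, filtering),
not an independent rediscovery claim.  UTR gene groups (40 ref-only / 60
both / 100 alt-only planted target genes over a 200-gene background,
500–1500 nt UTRs, 1–3 sites each, backgrounds rejection-sampled free of
both motifs — a slight compositional bias that is accepted) and a gene-set
annotation with one planted alt-only term complete the bundle.  Everything
derives from one seeded generator; identical seeds give byte-identical
files.

What passing synthetic tests does *not* show: performance on real genomes
(repeats, clustered/overlapping miRNAs, non-canonical hairpins), realistic
population genetics (no LD, no site-frequency spectrum), or agreement with
Turner-parameter folding.

The packaged six-locus fixture (`data/seed_loci_grch37_synthetic.tsv`) is a
labelled synthetic reconstruction: mature sequences, GRCh37 coordinates,
strands and alleles match the six publicly documented seed variants, but
hairpin loop, partner arm and flanks are constructed.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: enumeration cross-checks at n ≤ 12 (100 sequences), validity
sweeps of 300–1000 sequences at 60–260 nt, ORA permutation checks at 200
replicates, and end-to-end synthetic cohorts of 22 rare variants over 24
loci (the full 86-variant default remains available through
`SyntheticConfig()`).  Floating-point comparisons in tracebacks use an
absolute tolerance of 1e-7 against recomputed candidate scores; enumeration
agreement is asserted at 1e-9.  Degenerate inputs are defined errors:
empty sequences, non-ACGU characters, hairpins without matures, seeds not
exactly 7 nt, empty in-universe ORA queries.  An empty alternative target
set reports 0% new targets with a warning rather than dividing by zero.

## Known limitations

* The energy model is a documented stand-in; absolute energies and
  per-region impact percentages are not comparable to Turner-parameter
  tools.
* No GO-graph propagation or term-redundancy merging in ORA.
* No burden testing or sample-level association; the cohort summary is
  descriptive.
* Contig names must match across inputs (the validator suggests
  chr-prefix harmonization but the pipeline does not silently rename).
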