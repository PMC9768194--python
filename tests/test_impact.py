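"""Region assignment and structural-impact classification."""

import numpy as np
import pytest

from mirvar.genomic_io import (
    GenomicVariant, Mature, MirnaLocus, SequenceStore, reverse_complement,
    transcribe,
)
from mirvar.impact import (
    RegionMap, assign_regions, build_alignment, classify_impact,
    locate_variant,
)
from mirvar.rna_structure import DotBracket, mfe_fold
from mirvar.selection import intersect_mirna_variants
from mirvar.targeting import apply_variant_to_window

ARM = "GGCAGUGCAUCGGAUCCGUAGC"          # 22 nt, used as the 5p mature
HAIRPIN_RNA = ARM + "AAUAAAAUA" + reverse_complement(ARM, rna=True)
HAIRPIN_DNA = HAIRPIN_RNA.replace("U", "T")


def _toy_locus(strand="+", flank=20):
    """Perfect 53-pair stem hairpin with matures on both arms."""
    hlen = len(HAIRPIN_DNA)
    start = 1001
    plus = HAIRPIN_DNA if strand == "+" else reverse_complement(HAIRPIN_DNA)
    rng = np.random.default_rng(77)
    left = "".join(rng.choice(list("ACGT"), flank + 30))
    right = "".join(rng.choice(list("ACGT"), flank + 30))
    genome = SequenceStore({"c": (start - len(left), left + plus + right)})
    if strand == "+":
        m5 = Mature("5p", start + 1, start + 22)
        m3 = Mature("3p", start + hlen - 23, start + hlen - 2)
    else:
        hend = start + hlen - 1
        m5 = Mature("5p", hend - 22, hend - 1)
        m3 = Mature("3p", start + 1, start + 22)
    locus = MirnaLocus("mir-toy", "c", strand, (start, start + hlen - 1),
                       tuple(sorted((m5, m3), key=lambda m: m.start)),
                       high_confidence=True)
    return locus, genome


def _regions(strand="+", flank=20):
    locus, genome = _toy_locus(strand, flank)
    seq = transcribe(genome.fetch("c", *locus.window(flank), locus.strand))
    fold = mfe_fold(seq)
    return locus, genome, assign_regions(locus, fold, flank), fold


class TestAssignRegions:
    def test_regions_tile_window(self):
        locus, genome, regions, _ = _regions("+")
        L = len(regions)
        assert L == locus.hairpin_length + 2 * 20
        assert set(regions.base) == {"flank", "arm", "loop"}
        # flanks at the edges, loop strictly inside the hairpin
        assert regions.base[0] == "flank" and regions.base[-1] == "flank"
        loop_idx = [i for i, b in enumerate(regions.base) if b == "loop"]
        assert loop_idx and 20 + 22 < min(loop_idx) and max(loop_idx) < L - 20 - 22
        # seed = mature positions 2-8 of each arm
        for m in locus.matures:
            a, b = locus.mature_sense_interval(m, 20)
            assert all(regions.label(p) == "seed" for p in range(a + 1, a + 8))
            assert regions.label(a) == "mature"

    def test_strand_flip_equivalence(self):
        """The minus-strand locus yields the same region labels as the plus
        equivalent of the reverse-complemented sequence."""
        _, _, r_plus, _ = _regions("+")
        _, _, r_minus, _ = _regions("-")
        assert r_plus.base == r_minus.base
        assert np.array_equal(r_plus.mature_mask, r_minus.mature_mask)
        assert np.array_equal(r_plus.seed_mask, r_minus.seed_mask)

    def test_loop_matches_enumeration_oracle(self):
        """Structure-derived loop equals the unpaired stretch of the
        enumeration-optimal fold on a small perfect hairpin."""
        from oracles import enumerate_structures, loop_energy
        from mirvar.rna_structure import EnergyModel
        model = EnergyModel.default()
        seq = "GGCGCAAAAGCGCC"  # 5-pair stem, 4-nt loop (n=14)
        best = min(enumerate_structures(seq),
                   key=lambda s: loop_energy(seq, s, model))
        inner = max(best, key=lambda ij: ij[0])
        locus = MirnaLocus("t", "c", "+", (1, 14),
                           (Mature("5p", 1, 8),), high_confidence=True)
        regions = assign_regions(locus, mfe_fold(seq, model), flank=0)
        loop_pos = {i + 1 for i, b in enumerate(regions.base) if b == "loop"}
        assert loop_pos == set(range(inner[0] + 2, inner[1] + 1))

    def test_no_matures_is_error(self):
        locus = MirnaLocus("t", "c", "+", (1, 60), ())
        fold = DotBracket("A" * 60, "." * 60, ())
        with pytest.raises(ValueError, match="unusable"):
            assign_regions(locus, fold, 0)


class TestLocateVariant:
    @pytest.mark.parametrize("mature_pos,expected", [
        (5, "seed"),   # positions 2-8 rule
        (1, "mature"),
        (2, "seed"),
        (8, "seed"),
        (9, "mature"),
    ])
    def test_mature_position_rule(self, mature_pos, expected):
        locus, genome, regions, _ = _regions("+")
        m = locus.mature("5p")
        g = m.start + mature_pos - 1
        ref = genome.fetch("c", g, g)
        alt = "A" if ref != "A" else "C"
        (a,) = intersect_mirna_variants(
            [GenomicVariant("c", g, ref, alt)], [locus], 20)
        assert locate_variant(a, regions) == expected

    def test_deletion_spanning_boundary_takes_priority_label(self):
        """A deletion spanning the arm/mature boundary is labelled mature
        (the highest-priority affected position)."""
        locus, genome, regions, _ = _regions("+")
        m = locus.mature("3p")
        g = m.start - 2  # anchor; deletes m.start-1 (arm) and m.start (mature)
        ref = genome.fetch("c", g, g + 2)
        (a,) = intersect_mirna_variants(
            [GenomicVariant("c", g, ref, ref[0])], [locus], 20)
        labels = [regions.label(p) for p in range(a.sense_span[0],
                                                  a.sense_span[1] + 1)]
        assert "mature" in labels and "arm" in labels
        assert locate_variant(a, regions) == "mature"


class TestAlignment:
    def test_snv_alignment_is_identity(self):
        amap = build_alignment(10, 10, 4, 1, 1, "left")
        assert np.array_equal(amap, np.arange(10))

    def test_insertion_left_anchor(self):
        amap = build_alignment(10, 13, 4, 1, 4, "left")
        assert amap[4] == 4
        assert list(amap[5:8]) == [-1, -1, -1]
        assert list(amap[8:]) == [5, 6, 7, 8, 9]

    def test_insertion_right_anchor(self):
        amap = build_alignment(10, 13, 4, 1, 4, "right")
        assert amap[7] == 4
        assert list(amap[4:7]) == [-1, -1, -1]
        assert list(amap[8:]) == [5, 6, 7, 8, 9]

    def test_deletion(self):
        amap = build_alignment(10, 8, 4, 3, 1, "left")
        assert amap[4] == 4
        assert list(amap[5:]) == [7, 8, 9]


def _flat_regions(n, flank, seed_idx, mature_idx):
    base = ["flank"] * n
    for i in range(flank, n - flank):
        base[i] = "arm"
    mm = np.zeros(n, dtype=bool)
    sm = np.zeros(n, dtype=bool)
    mm[mature_idx] = True
    mm[seed_idx] = True
    sm[seed_idx] = True
    return RegionMap(tuple(base), mm, sm, flank, "t")


class TestClassifyImpact:
    def test_identical_structures_no_change(self):
        db = DotBracket.from_pairs("G" * 10 + "C" * 10, [(0, 19), (1, 18)])
        regions = _flat_regions(20, 2, [5], [6])
        amap = build_alignment(20, 20, 9, 1, 1)
        call = classify_impact(db, db, regions, amap, paradigm="MFE")
        assert call.impact == "no_change"
        assert call.changed_positions == ()

    def test_seed_variant_with_flank_only_change(self):
        """variant_region and impact are decoupled: a seed variant whose
        only structural change lies in the flank has impact 'flank'."""
        seq = "G" * 10 + "C" * 10
        ref = DotBracket.from_pairs(seq, [(0, 19), (5, 15)])
        alt = DotBracket.from_pairs(seq, [(5, 15)])  # flank pair 0-19 lost
        regions = _flat_regions(20, 2, seed_idx=[5], mature_idx=[5, 6, 7])
        amap = build_alignment(20, 20, 5, 1, 1)
        call = classify_impact(ref, alt, regions, amap,
                               variant_region="seed", paradigm="centroid")
        assert call.variant_region == "seed"
        assert call.impact == "flank"
        assert set(call.changed_positions) == {1, 20}

    def test_arm_snv_breaking_mature_partner_pair(self):
        """An SNV in one arm that breaks a stem pair whose partner lies in
        the mature on the other arm has impact 'mature'."""
        locus, genome, regions, ref_fold = _regions("+")
        # mutate a 5p-arm base that pairs into the 3p mature
        m5 = locus.mature("5p")
        g = m5.start + 11  # mature position 13 of the 5p arm (pairs into 3p)
        ref = genome.fetch("c", g, g)
        alt = {"A": "C", "C": "A", "G": "U", "U": "G"}.get(
            transcribe(ref), "A").replace("U", "T")
        v = GenomicVariant("c", g, ref, alt)
        we = apply_variant_to_window(locus, v, genome, 20)
        alt_fold = mfe_fold(we.alt_seq)
        (a,) = intersect_mirna_variants([v], [locus], 20)
        vr = locate_variant(a, regions)
        call = classify_impact(ref_fold, alt_fold, regions, we.alignment,
                               variant_region=vr, paradigm="MFE")
        assert call.impact in ("mature", "seed")
        sense_partner = [p for p in call.changed_positions
                         if regions.label(p) in ("mature", "seed")]
        assert sense_partner  # the 3p-mature partner side registered

    def test_neutral_loop_substitution_is_no_change(self):
        """A loop substitution that preserves every pair is no_change."""
        seq_ref = "GGGGGAAAACCCCC"
        seq_alt = "GGGGGAUAACCCCC"
        ref = mfe_fold(seq_ref)
        alt = mfe_fold(seq_alt)
        assert ref.structure == alt.structure
        regions = _flat_regions(14, 0, [6], [5, 6, 7])
        amap = build_alignment(14, 14, 6, 1, 1)
        call = classify_impact(ref, alt, regions, amap, paradigm="MFE")
        assert call.impact == "no_change"

    def test_inserted_paired_base_reports_nearest_ref_position(self):
        seq_ref = "GGGGAAAACCCC"
        ref = DotBracket.from_pairs(seq_ref, [(0, 11), (1, 10)])
        seq_alt = "GGGGGAAAACCCCC"
        # inserted G (idx 4) and C (idx 13) pair with each other
        alt = DotBracket.from_pairs(seq_alt, [(1, 12), (2, 11), (4, 13)])
        amap = np.array([0, 1, 2, 3, -1, 4, 5, 6, 7, 8, 9, 10, 11, -1])
        regions = _flat_regions(12, 0, [], [])
        call = classify_impact(ref, alt, regions, amap, paradigm="MFE")
        assert call.changed_positions  # insertion-created pairs reported
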