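"""Folding engines against brute-force enumeration and model invariants."""

import math
import random

import numpy as np
import pytest

from mirvar.rna_structure import (
    DotBracket, EnergyModel, centroid_structure, mea_structure, mfe_fold,
    nussinov_fold, partition_function,
)

from oracles import (
    best_mea_score, boltzmann_ensemble, enumerate_structures, loop_energy,
)


class TestNussinov:
    def test_min_loop_blocks_short_hairpins(self):
        assert nussinov_fold("GCGC").structure == "...."

    def test_simple_hairpin(self):
        db = nussinov_fold("GGGAAACCC")
        assert db.structure == "(((...)))"
        assert len(db.pairs) == 3

    def test_matches_enumeration_maximum(self):
        rng = random.Random(11)
        for _ in range(40):
            seq = "".join(rng.choice("ACGU")
                          for _ in range(rng.randint(5, 12)))
            best = max(len(s) for s in enumerate_structures(seq))
            db = nussinov_fold(seq)
            assert len(db.pairs) == best
            assert db.is_valid()

    def test_rejects_dna(self):
        with pytest.raises(ValueError):
            nussinov_fold("ACGT")


class TestMfe:
    def test_unpairable_sequence_is_open_chain(self, model):
        db = mfe_fold("AAAAACCCCC", model)
        assert db.structure == "." * 10
        assert db.energy == 0.0

    def test_matches_enumeration_minimum(self, model):
        rng = random.Random(3)
        for _ in range(30):
            seq = "".join(rng.choice("ACGU")
                          for _ in range(rng.randint(8, 12)))
            emin = min(loop_energy(seq, s, model)
                       for s in enumerate_structures(seq))
            db = mfe_fold(seq, model)
            assert db.is_valid()
            assert db.energy == pytest.approx(emin, abs=1e-9)
            # reported energy equals the independent score of the structure
            assert loop_energy(seq, set(db.pairs), model) == \
                pytest.approx(db.energy, abs=1e-9)

    def test_deterministic(self, model):
        seq = "GGGGAAAACCCCGGAAACCUUU"
        a = mfe_fold(seq, model)
        b = mfe_fold(seq, model)
        assert a.structure == b.structure and a.energy == b.energy


class TestPartitionFunction:
    def test_open_chain_only(self, model):
        pf = partition_function("AAAAAAAA", model)
        assert pf.Z == pytest.approx(1.0)
        assert np.all(pf.p == 0)
        assert np.all(pf.q == 1.0)

    def test_matches_enumeration(self, model):
        rng = random.Random(9)
        for _ in range(30):
            seq = "".join(rng.choice("ACGU")
                          for _ in range(rng.randint(6, 12)))
            Z, p, q = boltzmann_ensemble(seq, model)
            pf = partition_function(seq, model)
            assert pf.Z == pytest.approx(Z, rel=1e-9)
            assert np.allclose(np.triu(pf.p), p, atol=1e-9)
            assert np.allclose(pf.q, q, atol=1e-9)

    def test_mfe_member_bound(self, model):
        """Z >= exp(-E_MFE/kT): the MFE structure is one ensemble member."""
        rng = random.Random(21)
        for _ in range(10):
            seq = "".join(rng.choice("ACGU") for _ in range(40))
            e = mfe_fold(seq, model).energy
            pf = partition_function(seq, model)
            assert pf.lnZ >= -e / model.kT - 1e-9

    def test_conflicting_pairs_bounded(self, model):
        """Mutually exclusive pairs have total probability <= 1."""
        rng = random.Random(2)
        seq = "".join(rng.choice("ACGU") for _ in range(50))
        pf = partition_function(seq, model)
        # all pairs involving base i are mutually exclusive
        tot = pf.p.sum(axis=1)
        assert np.all(tot <= 1 + 1e-9)


class TestCentroidMea:
    def test_all_zero_probs_give_open_chain(self, model):
        pf = partition_function("AAAACCCCAA", model)
        assert centroid_structure(pf).structure == "." * 10
        mea = mea_structure(pf)
        assert mea.structure == "." * 10
        assert mea.score == pytest.approx(float(pf.q.sum()))

    def test_centroid_pairs_subset_of_strong_hairpin_mfe(self, model):
        seq = "GGGGGAAAACCCCC"
        pf = partition_function(seq, model)
        cen = centroid_structure(pf)
        mfe = mfe_fold(seq, model)
        assert set(cen.pairs) <= set(mfe.pairs)
        assert cen.is_valid()

    def test_mea_matches_enumeration(self, model):
        rng = random.Random(13)
        for _ in range(20):
            seq = "".join(rng.choice("ACGU")
                          for _ in range(rng.randint(6, 10)))
            pf = partition_function(seq, model)
            best = best_mea_score(seq, pf.p, pf.q, 1.0, model.min_loop)
            mea = mea_structure(pf, 1.0)
            assert mea.score == pytest.approx(best, abs=1e-9)
            assert mea.is_valid()

    def test_small_gamma_prefers_unpaired(self, model):
        seq = "GGGGGAAAACCCCC"
        pf = partition_function(seq, model)
        mea = mea_structure(pf, gamma=1e-6)
        assert mea.structure == "." * len(seq)


class TestEnergyModel:
    def test_yaml_roundtrip(self, model, tmp_path):
        import yaml
        from importlib import resources
        text = resources.files("mirvar").joinpath(
            "data/energy_params.yaml").read_text()
        p = tmp_path / "m.yaml"
        p.write_text(text)
        m2 = EnergyModel.from_yaml(p)
        assert np.array_equal(m2.stack, model.stack)
        assert m2.kT == model.kT

    def test_invalid_parameters_rejected(self, model):
        import dataclasses
        with pytest.raises(ValueError):
            dataclasses.replace(model, min_loop=2)
        with pytest.raises(ValueError):
            dataclasses.replace(model, stack=np.abs(model.stack))

    def test_degenerate_stack_model_maximizes_stacks(self):
        """With unit stacking and vanishing loop penalties the MFE energy
        equals minus the largest stack count over all structures."""
        eps = 1e-6
        model = EnergyModel(
            stack=np.full((6, 6), -1.0),
            hairpin_loop={3: eps}, bulge_loop={1: eps},
            internal_loop={2: eps}, extrapolation_slope=1e-9,
            ml_init=eps, ml_branch=eps, ml_unpaired=eps,
        )
        rng = random.Random(4)
        for _ in range(15):
            seq = "".join(rng.choice("ACGU")
                          for _ in range(rng.randint(8, 12)))
            best = min(loop_energy(seq, s, model)
                       for s in enumerate_structures(seq))
            db = mfe_fold(seq, model)
            assert db.energy == pytest.approx(best, abs=1e-6)


class TestViennaCrossCheck:
    def test_strong_hairpins_agree_with_rnafold(self, model):
        """On near-perfect stems the simplified model recovers the same
        helix as ViennaRNA's Turner-parameter fold (independent external
        implementation; qualitative check only — the models differ)."""
        import subprocess
        rng = random.Random(1)
        for _ in range(5):
            arm = "".join(rng.choice("ACGU") for _ in range(20))
            comp = arm.translate(str.maketrans("ACGU", "UGCA"))[::-1]
            seq = arm + "AAUAA" + comp
            mine = set(mfe_fold(seq, model).pairs)
            out = subprocess.run(["RNAfold", "--noPS"], input=seq,
                                 capture_output=True, text=True).stdout
            vstruct = out.splitlines()[1].split()[0]
            stack, vienna = [], set()
            for i, c in enumerate(vstruct):
                if c == "(":
                    stack.append(i)
                elif c == ")":
                    vienna.add((stack.pop(), i))
            assert len(mine & vienna) / len(mine) >= 0.8


class TestDotBracket:
    def test_validation_catches_defects(self):
        assert DotBracket("GGGAAACCC", "(((...)))",
                          ((0, 8), (1, 7), (2, 6))).is_valid()
        assert not DotBracket("GGGAAACCC", "(((...).)",
                              ((0, 8), (1, 6), (2, 6))).is_valid()
        # min-loop violation
        assert not DotBracket("GGAC", "(..)", ((0, 3),)).is_valid()

    def test_vienna_rendering(self):
        db = DotBracket("GGGAAACCC", "(((...)))",
                        ((0, 8), (1, 7), (2, 6)), energy=-3.25)
        assert db.to_vienna() == "GGGAAACCC\n(((...))) ( -3.25)"
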