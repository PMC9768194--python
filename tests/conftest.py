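import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mirvar.rna_structure import EnergyModel
from mirvar.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def model():
    return EnergyModel.default()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic cohort shared across tests (fixed seed)."""
    cfg = SyntheticConfig(
        seed=42, n_samples=30, n_mirnas=16, n_low_confidence=3,
        rare_region_counts={"flank": 2, "arm": 4, "loop": 2, "mature": 4,
                            "seed": 3},
        n_rare_hom=2, n_common=6, n_decoy=6,
        n_ref_only=10, n_both=15, n_alt_only=25, n_background=40,
        n_terms=12, panel_size=30,
    )
    outdir = tmp_path_factory.mktemp("simdata")
    paths, truth = generate_dataset(cfg, outdir)
    return cfg, paths, truth
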