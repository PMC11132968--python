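import gffutils
import numpy as np
import pytest

import gemmatlas as g

RULE_UTR_LENGTHS = [100, 499, 500, 2999, 3000, 3500, 200]
N_RUN_GENE_INDEX = 6  # last gene carries a planted N-run near its TSS


@pytest.fixture(scope="session")
def archetypes():
    return g.standard_archetypes()


@pytest.fixture(scope="session")
def rule_genome():
    """Toy genome exercising every branch of the part-design rule table."""
    return g.make_toy_genome(
        RULE_UTR_LENGTHS,
        plant_sites={0: [("BsaI", 400)], 2: [("SapI", 900)]},
        plant_n_runs={N_RUN_GENE_INDEX: (300, 3)},
        seed=20240101,
    )


@pytest.fixture(scope="session")
def rule_db(rule_genome):
    return gffutils.create_db(
        rule_genome.gff_text, ":memory:", from_string=True,
        force=True, keep_order=True,
    )


@pytest.fixture(scope="session")
def clean_gemma():
    """Noise-free synthetic gemma with a sharp notch-peaked reporter."""
    return g.make_gemma_image("scz-narrow", noise=g.NoiseParams.none(), seed=5)


def scalar_landmarks(truth):
    lm = truth.landmarks
    from gemmatlas.imaging import LandmarkSet

    return LandmarkSet(lm.start[0], lm.notch1[0], lm.notch2[0], lm.end[0], scalar=True)


def folded_reference(archetype, grid_n=500):
    """Archetype folded about the axis midpoint and max-normalized."""
    x = np.linspace(0.0, 1.0, grid_n)
    ref = archetype(x)
    half = (grid_n + 1) // 2
    folded = (ref[:half] + ref[::-1][:half]) / 2.0
    return folded / folded.max()
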