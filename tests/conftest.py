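import numpy as np
import pytest

from nemafauna import CommunityMatrix, CommunitySample, default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_sample(counts, sample_id="s1", treatment="CK", depth_layer="0-5",
                replicate=1, fresh_mass=60.0, water_content=0.4):
    return CommunitySample(
        sample_id=sample_id, treatment=treatment, depth_layer=depth_layer,
        replicate=replicate, fresh_mass=fresh_mass,
        water_content=water_content, counts=counts,
    )


@pytest.fixture
def small_matrix(taxonomy):
    """Two treatments x two replicates, one layer, mixed guilds."""
    samples = [
        make_sample({"Acrobeloides": 12, "Aphelenchus": 4, "Rotylenchus": 6,
                     "Eudorylaimus": 3}, "CK-R1", "CK", replicate=1),
        make_sample({"Acrobeloides": 10, "Aphelenchus": 5, "Rotylenchus": 7,
                     "Eudorylaimus": 2}, "CK-R2", "CK", replicate=2),
        make_sample({"Acrobeles": 20, "Ditylenchus": 6, "Helicotylenchus": 3,
                     "Labronemella": 5}, "D-R1", "D", replicate=1),
        make_sample({"Acrobeles": 18, "Ditylenchus": 7, "Helicotylenchus": 4,
                     "Labronemella": 6}, "D-R2", "D", replicate=2),
    ]
    return CommunityMatrix(samples, taxonomy)
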