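from pathlib import Path

import pytest

from resorb.simulate import SyntheticTruth, generate_leaf_dataset
from resorb.io import samples_to_frame
from resorb.tree import Phylogeny

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def three_tip_tree() -> Phylogeny:
    """The worked 3-tip example: ((A:1,B:1):1,C:2)."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def family_tree_path() -> Path:
    """Synthetic stand-in for the survey's 36-species / 15-family tree
    (the field phylogeny is not deposited)."""
    return DATA / "synthetic_36sp_15fam.nwk"


@pytest.fixture(scope="session")
def default_truth() -> SyntheticTruth:
    return SyntheticTruth.default(seed=42)


@pytest.fixture(scope="session")
def default_dataset(default_truth):
    samples = generate_leaf_dataset(default_truth)
    return samples_to_frame(samples)
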