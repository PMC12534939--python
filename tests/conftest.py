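import random

import pytest

from smilesalign import fixtures as fx
from smilesalign.molecule_io import AtomToken, ChargeBlueprint
from smilesalign.scoring import build_all_vs_all, build_paired, build_scoring_matrix


def make_blueprint(charges, elements=None, molecule_id="synthetic"):
    """Hand-built blueprint for DP tests that need exact charges."""
    if elements is None:
        elements = ["C"] * len(charges)
    tokens = [
        AtomToken(symbol=e, element=e, atom_index=i, span=(i, i + 1))
        for i, e in enumerate(elements)
    ]
    return ChargeBlueprint(
        molecule_id=molecule_id,
        canonical_smiles="".join(elements),
        tokens=tokens,
        charges=list(charges),
        skeleton="\x00" * len(charges),
    )


def random_toy_matrix(rng: random.Random):
    """A structurally valid scoring matrix from a random difference pool."""
    diffs = [rng.uniform(0.0, 3.0) for _ in range(rng.randint(2, 12))]
    return build_scoring_matrix(diffs)


@pytest.fixture(scope="session")
def combined_blueprints():
    return fx.corpus_blueprints(fx.combined_corpus())


@pytest.fixture(scope="session")
def all_matrix(combined_blueprints):
    return build_all_vs_all(combined_blueprints)


@pytest.fixture(scope="session")
def paired_set(combined_blueprints):
    return build_paired(combined_blueprints, min_pair_observations=100)


@pytest.fixture(scope="session")
def krebs_pathway():
    return fx.builtin_pathway("krebs")


@pytest.fixture(scope="session")
def glycolysis_pathway():
    return fx.builtin_pathway("glycolysis")
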