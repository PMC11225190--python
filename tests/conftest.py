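import numpy as np
import pytest

from phenobin.chardata import CharacterMatrix, CharacterSpec
from phenobin.tree import ReferenceTree


@pytest.fixture
def quartet_tree() -> ReferenceTree:
    return ReferenceTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def five_taxon_tree() -> ReferenceTree:
    return ReferenceTree.from_newick(
        "(((A:0.2,B:0.3):0.4,(C:0.25,D:0.35):0.3):0.2,E:0.6);"
    )


def make_matrix(ids, states, specs=None, missing=None, taxa=None, is_reference=None):
    """Small helper to build a CharacterMatrix from plain lists."""
    states = np.asarray(states, dtype=int)
    n, c = states.shape
    if specs is None:
        k = int(states.max()) + 1
        kind = "binary" if k <= 2 else "ordered_multistate"
        specs = [
            CharacterSpec(id=f"c{j + 1}", kind=kind, n_states=max(k, 2))
            for j in range(c)
        ]
    return CharacterMatrix(
        specimen_ids=list(ids),
        taxon_labels=list(taxa) if taxa is not None else list(ids),
        is_reference=(
            np.asarray(is_reference, dtype=bool)
            if is_reference is not None
            else np.ones(n, dtype=bool)
        ),
        states=states,
        missing_mask=(
            np.asarray(missing, dtype=bool)
            if missing is not None
            else np.zeros_like(states, dtype=bool)
        ),
        specs=specs,
    )
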