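import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from matloci.io import SpeciesAlignment


def make_alignment(seqs: dict[str, str], species=None, gene_id="g", alphabet="dna"):
    """Small helper: alignment with default species labels A*/B* by prefix."""
    if species is None:
        species = {s: ("speciesA" if s.startswith("A") else "speciesB") for s in seqs}
    return SpeciesAlignment(
        gene_id=gene_id, seqs=seqs, alphabet=alphabet, species_of=species
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(rng, n=6, L=60, gap_frac=0.05, n_frac=0.03):
    """Random DNA alignment with sprinkled gaps and Ns, split A/B."""
    bases = np.array(list("ACGT"))
    seqs = {}
    for i in range(n):
        row = rng.choice(bases, size=L)
        mask = rng.random(L) < gap_frac
        row[mask] = "-"
        mask = rng.random(L) < n_frac
        row[mask] = "N"
        name = ("A" if i < n // 2 else "B") + f"{i:02d}"
        seqs[name] = "".join(row)
    return make_alignment(seqs)
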