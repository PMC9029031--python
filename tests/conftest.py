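import numpy as np
import pytest

from barcodeval.io import AlignedDataset, SequenceRecord, TaxonomyTable
from barcodeval.k2p import DistanceMatrix


def make_dataset(entries, genus=None, subfamily=None, complexes=None):
    """Build an AlignedDataset from (id, species, sequence) triples.

    Species not covered by the ``genus``/``subfamily`` dicts fall into a
    single default genus/subfamily.
    """
    species = {sp for _, sp, _ in entries}
    genus = {**{sp: "GenusX" for sp in species}, **(genus or {})}
    subfamily = {**{sp: "SubfamX" for sp in species}, **(subfamily or {})}
    taxonomy = TaxonomyTable(genus=genus, subfamily=subfamily, complex=complexes or {})
    records = [SequenceRecord(i, sp, seq) for i, sp, seq in entries]
    return AlignedDataset(records=records, taxonomy=taxonomy)


def make_dm(species, d, L=100):
    """Build a DistanceMatrix directly from a square distance array
    (NaN = undefined pair); P/Q bookkeeping is zero-filled."""
    d = np.asarray(d, dtype=float)
    n = len(species)
    assert d.shape == (n, n)
    defined = ~np.isnan(d)
    return DistanceMatrix(
        ids=[f"q{i}" for i in range(n)],
        species=np.asarray(species, dtype=object),
        d=d,
        L=np.full((n, n), L, dtype=int),
        P=np.zeros((n, n)),
        Q=np.zeros((n, n)),
        defined=defined,
    )


@pytest.fixture
def two_species_toy():
    """2 species × 2 sequences with hand-controllable distances via
    site differences on a 200 bp alignment."""
    base = "ACGT" * 50

    def mutate(seq, positions, to="G"):
        s = list(seq)
        for p in positions:
            s[p] = to if s[p] != to else "C"
        return "".join(s)

    entries = [
        ("a1", "spA", base),
        ("a2", "spA", mutate(base, [0])),          # 1 diff from a1
        ("b1", "spB", mutate(base, range(20, 30))),  # 10 diffs from base
        ("b2", "spB", mutate(base, range(20, 32))),  # 12 diffs from base
    ]
    return make_dataset(entries)
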