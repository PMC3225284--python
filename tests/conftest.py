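import pytest

from cbcmap.io import Dataset, PairedAlignment, PairTable, read_tree
from cbcmap.simulate import make_two_species_fixture


@pytest.fixture(scope="session")
def two_species_dataset() -> Dataset:
    return make_two_species_fixture()


@pytest.fixture()
def toy_dataset() -> Dataset:
    """Four taxa, one paired + one unpaired variable column.

    Columns (0-based): 0 pairs with 3; 1 and 2 unpaired.  Taxon A differs at
    columns 0 (G->A, paired) and 1 (C->U, unpaired).
    """
    alignment = PairedAlignment(
        taxa=("A", "B", "C", "D"),
        rows=("AUGC", "GCGC", "GCGC", "GCGC"),
    )
    structure = PairTable(
        pairs=((0, 3),), conserved=(True,), helix=(1,), n_columns=4
    )
    tree = read_tree("((A,B),(C,D));", taxa=["A", "B", "C", "D"])
    return Dataset(alignment=alignment, structure=structure, tree=tree)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
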