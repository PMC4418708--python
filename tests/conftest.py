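import numpy as np
import pytest

from dmipred.io import ElmClassDef, PairSet, ProteinRecord
from dmipred.structure import Atom, Residue, Structure, TemplateComplex


@pytest.fixture
def toy_proteome() -> list[ProteinRecord]:
    rng = np.random.default_rng(42)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    return [
        ProteinRecord(f"P{i}", "".join(rng.choice(aa, size=n)))
        for i, n in enumerate([60, 80, 100])
    ]


@pytest.fixture
def elm_class() -> ElmClassDef:
    return ElmClassDef("LIG_TEST_1", "PF00001", "P..P")


def point_residue(chain: str, resnum: int, xyz, element: str = "C", name: str = "CA") -> Residue:
    return Residue(chain, resnum, "", "ALA", (Atom(name, element, *xyz),))


def two_chain_complex(gap: float) -> TemplateComplex:
    """A 3-residue PRD whose first residue sits exactly ``gap`` Å below the
    peptide strand; the other PRD residues extend away from the interface."""
    prd = [point_residue("A", i + 1, (-4.0 * i, 0.0, 0.0)) for i in range(3)]
    pep = [point_residue("B", j + 1, (4.0 * j, 0.0, gap)) for j in range(5)]
    return TemplateComplex("T", Structure({"A": prd, "B": pep}), "A", "B")


@pytest.fixture
def small_pair_set() -> PairSet:
    tp = [(f"A{i}", f"B{i}") for i in range(10)]
    tn = [(f"C{i}", f"D{i}") for i in range(100)]
    return PairSet(tp, tn)
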