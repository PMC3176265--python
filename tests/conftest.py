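import numpy as np
import pytest

from ppihotspot.structure_io import Atom, Residue, ResidueKey, Structure
from ppihotspot.synthetic import (
    EngineeredContact,
    ToyComplexSpec,
    make_toy_complex,
)


def make_structure(pdb_id, chain_residues):
    """Build a Structure from {chain: [(resname, resseq, {atom: coord})]}."""
    s = Structure(pdb_id=pdb_id)
    from ppihotspot.structure_io import one_letter

    for chain_id, residues in chain_residues.items():
        s.chains[chain_id] = []
        for resname, resseq, atoms in residues:
            key = ResidueKey(pdb_id, chain_id, resseq, "", one_letter(resname))
            res = Residue(key=key, resname=resname)
            for name, coord in atoms.items():
                element = "S" if name.startswith("S") else name[0]
                res.atoms.append(Atom(name=name, element=element,
                                      coord=tuple(coord)))
            s.chains[chain_id].append(res)
    return s


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory):
    """Toy complex with one engineered salt bridge and one hydrogen bond."""
    spec = ToyComplexSpec(
        n_residues_per_chain=6,
        gap=4.5,
        contacts=(
            EngineeredContact("salt_bridge", 1, 1, 6.5),
            EngineeredContact("hbond", 4, 4, 2.9),
        ),
    )
    path = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    path.write_text(make_toy_complex(spec))
    return path


@pytest.fixture(scope="session")
def separated_pdb(tmp_path_factory):
    """Two chains 100 A apart: no interface at all."""
    spec = ToyComplexSpec(n_residues_per_chain=5, gap=100.0)
    path = tmp_path_factory.mktemp("pdb") / "separated.pdb"
    path.write_text(make_toy_complex(spec))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
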