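"""PDB structure model: parsing, partner splitting, sequence extraction.

Coordinates and residue numbering follow PDB author numbering (chain id,
residue sequence number, insertion code). Hydrogens and waters are dropped
on input; only the first model of multi-model files is read; for alternate
locations the highest-occupancy conformer is kept (ties broken by order of
appearance, which for PDB files is altloc 'A' first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "ResidueKey",
    "Residue",
    "Structure",
    "PartnerSpec",
    "PdbFormatError",
    "read_pdb",
    "split_partners",
    "extract_sequence",
    "THREE_TO_ONE",
]


class PdbFormatError(ValueError):
    """Raised for unparsable or empty PDB input."""


#: Standard residues plus common modified-residue parents (MSE -> MET etc.).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues mapped to their parent amino acid
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    """A heavy atom with author PDB metadata. Coordinates in Angstrom."""

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self):
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue within a complex."""

    pdb_id: str
    chain_id: str
    resseq: int
    icode: str = ""
    aa: str = "X"


@dataclass
class Residue:
    key: ResidueKey
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """Chains -> residues -> atoms, in file order."""

    pdb_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self):
        for residues in self.chains.values():
            yield from residues

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def get_residue(self, key: ResidueKey) -> Residue:
        for res in self.chains.get(key.chain_id, []):
            k = res.key
            if (k.resseq, k.icode) == (key.resseq, key.icode):
                return res
        raise KeyError(f"residue {key} not in structure {self.pdb_id}")

    def coord_array(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms()]
        return np.array(coords, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class PartnerSpec:
    """Chain groups defining the two binding partners of a complex."""

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __init__(self, side_a, side_b):
        object.__setattr__(self, "side_a", frozenset(side_a))
        object.__setattr__(self, "side_b", frozenset(side_b))
        if not self.side_a or not self.side_b:
            raise ValueError("both partner sides must be non-empty")
        if self.side_a & self.side_b:
            raise ValueError(
                f"partner sides overlap: {sorted(self.side_a & self.side_b)}"
            )

    @classmethod
    def parse(cls, text: str) -> "PartnerSpec":
        """Parse 'AB:C' style chain-group notation."""
        try:
            a, b = text.split(":")
        except ValueError:
            raise ValueError(f"partner spec must be 'chains:chains', got {text!r}")
        return cls(set(a), set(b))

    def side_of(self, chain_id: str) -> str:
        if chain_id in self.side_a:
            return "a"
        if chain_id in self.side_b:
            return "b"
        raise KeyError(f"chain {chain_id!r} not in partner spec")


def one_letter(resname: str) -> str:
    return THREE_TO_ONE.get(resname.upper(), "X")


def read_pdb(path, pdb_id: str | None = None, keep_hetero: bool = False) -> Structure:
    """Read a PDB file into a normalized :class:`Structure`.

    Normalization: model 1 only; hydrogens/deuteriums removed; waters
    removed; other HETATM groups dropped unless ``keep_hetero``; for
    alternate locations only the highest-occupancy conformer is kept.
    """
    path = str(path)
    try:
        pdb_file = PDBFile.read(path)
        arr = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises various parse errors
        raise PdbFormatError(f"cannot parse PDB file {path}: {exc}") from exc

    mask = ~np.isin(arr.element, ("H", "D"))
    mask &= ~np.isin(arr.res_name, tuple(_WATER_NAMES))
    if not keep_hetero:
        mask &= ~arr.hetero
    arr = arr[mask]
    if arr.array_length() == 0:
        raise PdbFormatError(f"no atoms remain after normalization of {path}")

    if pdb_id is None:
        import os

        pdb_id = os.path.splitext(os.path.basename(path))[0][:4].lower()

    structure = Structure(pdb_id=pdb_id)
    seen: set[tuple[str, int, str]] = set()
    res: Residue | None = None
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        rid = (cid, int(arr.res_id[i]), str(arr.ins_code[i]).strip())
        if res is None or rid != (res.key.chain_id, res.key.resseq, res.key.icode):
            if rid in seen:
                raise PdbFormatError(
                    f"duplicate residue {rid} in {path} (non-contiguous records)"
                )
            seen.add(rid)
            resname = str(arr.res_name[i])
            key = ResidueKey(
                pdb_id=pdb_id, chain_id=cid, resseq=rid[1], icode=rid[2],
                aa=one_letter(resname),
            )
            res = Residue(key=key, resname=resname)
            structure.chains.setdefault(cid, []).append(res)
        res.atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                coord=tuple(float(x) for x in arr.coord[i]),
                occupancy=float(arr.occupancy[i]),
                is_hetero=bool(arr.hetero[i]),
            )
        )
    return structure


def split_partners(s: Structure, spec: PartnerSpec) -> tuple[Structure, Structure]:
    """Split a complex into its two binding partners, coordinates unchanged."""
    missing = (spec.side_a | spec.side_b) - set(s.chains)
    if missing:
        raise ValueError(
            f"partner spec chains {sorted(missing)} absent from {s.pdb_id} "
            f"(has {sorted(s.chains)})"
        )
    side_a = Structure(pdb_id=s.pdb_id, chains={
        c: s.chains[c] for c in s.chains if c in spec.side_a
    })
    side_b = Structure(pdb_id=s.pdb_id, chains={
        c: s.chains[c] for c in s.chains if c in spec.side_b
    })
    return side_a, side_b


def extract_sequence(s: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain in residue order (nonstandard -> 'X')."""
    if chain_id not in s.chains:
        raise KeyError(f"chain {chain_id!r} not in structure {s.pdb_id}")
    return "".join(one_letter(r.resname) for r in s.chains[chain_id])
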