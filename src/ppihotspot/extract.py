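"""Per-residue feature extraction for one two-partner complex.

Runs the burial (SASA), contact and sequence feature families over every
residue of a complex and assembles the per-residue CSV consumed by
:func:`ppihotspot.dataset.assemble`. Sequence features are keyed to
structure residues by position: when the structure chain sequence and
the profile/alignment query differ, they are reconciled by pairwise
global alignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import contacts as _contacts
from . import sasa as _sasa
from .seqfeat import (
    PSSM_COLUMNS,
    PssmProfile,
    conservation_grade,
    msa_columns,
    physchem,
    sequence_entropy,
)
from .structure_io import PartnerSpec, Structure

__all__ = ["extract_features", "map_positions"]


def map_positions(struct_seq: str, query_seq: str) -> dict[int, int]:
    """Map chain residue indices onto profile/alignment positions.

    Identical sequences map index-to-index; otherwise a global pairwise
    alignment (BLOSUM62) reconciles numbering differences such as
    truncated termini or point substitutions.
    """
    if struct_seq == query_seq:
        return {i: i for i in range(len(struct_seq))}
    import biotite.sequence as seq
    import biotite.sequence.align as align

    s1 = seq.ProteinSequence(struct_seq.replace("X", "A"))
    s2 = seq.ProteinSequence(query_seq.replace("X", "A"))
    matrix = align.SubstitutionMatrix.std_protein_matrix()
    ali = align.align_optimal(s1, s2, matrix, gap_penalty=(-10, -1))[0]
    mapping = {}
    for i, j in ali.trace:
        if i != -1 and j != -1:
            mapping[int(i)] = int(j)
    return mapping


def extract_features(
    complex_structure: Structure,
    spec: PartnerSpec,
    pssm_by_chain: dict[str, PssmProfile] | None = None,
    msa_by_chain: dict[str, list[str]] | None = None,
    consurf_by_chain: dict[str, np.ndarray] | None = None,
    n_sphere_points: int = 960,
) -> pd.DataFrame:
    """Per-residue feature table for every residue of the complex.

    Missing sequence-feature sources leave the corresponding columns as
    NaN (imputed downstream at model-assembly time). Physicochemical
    constants are NaN for nonstandard ('X') residues.
    """
    pssm_by_chain = pssm_by_chain or {}
    msa_by_chain = msa_by_chain or {}
    consurf_by_chain = consurf_by_chain or {}

    sasa_cache: dict = {}
    a, b = None, None
    rows = []

    # per-chain sequence feature vectors, aligned to structure residues
    chain_maps: dict[str, dict[int, int]] = {}
    chain_entropy: dict[str, list] = {}
    chain_grades: dict[str, np.ndarray] = {}
    from .structure_io import extract_sequence

    for cid in complex_structure.chain_ids:
        struct_seq = extract_sequence(complex_structure, cid)
        if cid in pssm_by_chain:
            chain_maps[cid] = map_positions(
                struct_seq, pssm_by_chain[cid].query
            )
        if cid in msa_by_chain:
            seqs = msa_by_chain[cid]
            query = seqs[0].replace("-", "")
            m = map_positions(struct_seq, query)
            # alignment columns are indexed by ungapped query position
            colmap, qpos = {}, 0
            for col, c in enumerate(seqs[0]):
                if c != "-":
                    colmap[qpos] = col
                    qpos += 1
            ent = [sequence_entropy(col) for col in msa_columns(seqs)]
            chain_entropy[cid] = [
                ent[colmap[m[i]]] if i in m and m[i] in colmap else None
                for i in range(len(struct_seq))
            ]
            if cid not in consurf_by_chain:
                chain_grades[cid] = conservation_grade(seqs)
                chain_maps.setdefault(cid, m)
        if cid in consurf_by_chain:
            chain_grades[cid] = np.asarray(consurf_by_chain[cid])
            chain_maps.setdefault(
                cid, {i: i for i in range(len(struct_seq))}
            )

    if a is None:
        from .structure_io import split_partners

        a, b = split_partners(complex_structure, spec)

    for cid in complex_structure.chain_ids:
        for i, res in enumerate(complex_structure.chains[cid]):
            key = res.key
            asa = _sasa.residue_asa_features(
                complex_structure, spec, key,
                n_points=n_sphere_points, _cache=sasa_cache,
            )
            cc = _contacts.ContactCounts(
                n_hbonds=_contacts.hydrogen_bonds(a, b, key),
                n_salt_bridges=_contacts.salt_bridges(a, b, key),
                n_atomic_contacts=_contacts.atomic_contacts(a, b, key),
            )
            row = {
                "pdb_id": key.pdb_id,
                "chain": key.chain_id,
                "resseq": key.resseq,
                "icode": key.icode,
                "aa": key.aa,
                "asa_monomer": asa.asa_monomer,
                "asa_complex": asa.asa_complex,
                "delta_asa": asa.delta_asa,
                "delta_asa_pct": (np.nan if asa.delta_asa_pct is None
                                  else asa.delta_asa_pct),
                "rel_asa": asa.rel_asa,
                "is_interface": asa.is_interface,
                "n_hbonds": cc.n_hbonds,
                "n_salt_bridges": cc.n_salt_bridges,
                "n_atomic_contacts": cc.n_atomic_contacts,
            }
            try:
                pc = physchem(key.aa)
                for name, val in zip(
                    ("hydrophobicity", "hydrophilicity", "polarity",
                     "polarizability", "propensity", "avg_asa"),
                    pc.as_array(),
                ):
                    row[name] = val
            except KeyError:
                for name in ("hydrophobicity", "hydrophilicity", "polarity",
                             "polarizability", "propensity", "avg_asa"):
                    row[name] = np.nan

            profile = pssm_by_chain.get(cid)
            pmap = chain_maps.get(cid, {})
            if profile is not None and i in pmap and pmap[i] < len(profile):
                norm = profile.normalized[pmap[i]]
                for aa_code, val in zip(PSSM_COLUMNS, norm):
                    row[f"pssm_{aa_code}"] = val
            else:
                for aa_code in PSSM_COLUMNS:
                    row[f"pssm_{aa_code}"] = np.nan

            ent = chain_entropy.get(cid)
            if ent is not None and i < len(ent) and ent[i] is not None:
                row["sequence_entropy"] = ent[i]
            else:
                row["sequence_entropy"] = np.nan

            grades = chain_grades.get(cid)
            gmap = chain_maps.get(cid, {})
            if (grades is not None and i in gmap
                    and gmap[i] < len(grades) and grades[gmap[i]] > 0):
                row["conservation_grade"] = float(grades[gmap[i]])
            else:
                row["conservation_grade"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
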