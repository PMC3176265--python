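"""Sequence-derived residue features.

Four feature families:

* physicochemical constants (six AAindex entries per residue type);
* position-specific scoring matrix (PSSM) columns from PSI-BLAST ASCII
  output, squashed to (0,1) with the logistic 1/(1+e^-x);
* sequence entropy of an alignment column, Shannon entropy over the 20
  amino acids normalized to 0-100 (0 = invariant column);
* evolutionary conservation grade on the ConSurf 1-9 colour scale
  (9 = conserved), either parsed from a grades file or approximated by
  binning per-column entropies into nine within-protein quantiles.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AA_ORDER",
    "PSSM_COLUMNS",
    "PHYSCHEM_TABLE",
    "PHYSCHEM_NAMES",
    "PhysChemVector",
    "PssmProfile",
    "physchem",
    "parse_pssm",
    "normalize_pssm",
    "sequence_entropy",
    "conservation_grade",
    "entropy_to_grades",
    "parse_consurf_grades",
    "parse_fasta_msa",
    "PssmFormatError",
]

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Column order of PSI-BLAST ASCII PSSMs (first score block).
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

PHYSCHEM_NAMES = (
    "hydrophobicity", "hydrophilicity", "polarity",
    "polarizability", "propensity", "avg_asa",
)

#: Six physicochemical scales per amino acid, keyed by AAindex accession:
#: KYTJ820101 (Kyte-Doolittle hydropathy), HOPT810101 (Hopp-Woods
#: hydrophilicity), GRAR740102 (Grantham polarity), CHAM820101 (Charton
#: polarizability), CHOP780202 (Chou-Fasman beta-sheet propensity),
#: JANJ780101 (Janin average accessible surface area).
PHYSCHEM_TABLE: dict[str, tuple[float, ...]] = {
    #      hydroph hydrophil polar  polariz propen avg_asa
    "A": ( 1.8, -0.5,  8.1, 0.046, 0.83,  27.8),
    "R": (-4.5,  3.0, 10.5, 0.291, 0.93,  94.7),
    "N": (-3.5,  0.2, 11.6, 0.134, 0.89,  60.1),
    "D": (-3.5,  3.0, 13.0, 0.105, 0.54,  60.6),
    "C": ( 2.5, -1.0,  5.5, 0.128, 1.19,  15.5),
    "Q": (-3.5,  0.2, 10.5, 0.180, 1.10,  68.7),
    "E": (-3.5,  3.0, 12.3, 0.151, 0.37,  68.2),
    "G": (-0.4,  0.0,  9.0, 0.000, 0.75,  24.5),
    "H": (-3.2, -0.5, 10.4, 0.230, 0.87,  50.7),
    "I": ( 4.5, -1.8,  5.2, 0.186, 1.60,  22.8),
    "L": ( 3.8, -1.8,  4.9, 0.186, 1.30,  27.6),
    "K": (-3.9,  3.0, 11.3, 0.219, 0.74, 103.0),
    "M": ( 1.9, -1.3,  5.7, 0.221, 1.05,  33.5),
    "F": ( 2.8, -2.5,  5.2, 0.290, 1.38,  25.5),
    "P": (-1.6,  0.0,  8.0, 0.131, 0.55,  51.5),
    "S": (-0.8,  0.3,  9.2, 0.062, 0.75,  42.0),
    "T": (-0.7, -0.4,  8.6, 0.108, 1.19,  45.0),
    "W": (-0.9, -3.4,  5.4, 0.409, 1.37,  34.7),
    "Y": (-1.3, -2.3,  6.2, 0.298, 1.47,  55.2),
    "V": ( 4.2, -1.5,  5.9, 0.140, 1.70,  23.7),
}


class PssmFormatError(ValueError):
    """Raised for malformed PSI-BLAST ASCII PSSM input."""


@dataclass(frozen=True)
class PhysChemVector:
    hydrophobicity: float
    hydrophilicity: float
    polarity: float
    polarizability: float
    propensity: float
    avg_asa: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PHYSCHEM_NAMES])


def physchem(aa: str) -> PhysChemVector:
    """Six physicochemical constants for a standard amino-acid type."""
    try:
        values = PHYSCHEM_TABLE[aa.upper()]
    except KeyError:
        raise KeyError(
            f"no physicochemical constants for residue type {aa!r}; "
            "caller must impute nonstandard residues"
        )
    return PhysChemVector(*values)


@dataclass
class PssmProfile:
    """Raw PSSM substitution scores with logistic normalization."""

    query: str
    scores: np.ndarray = field(repr=False)   # (L, 20) integers, PSSM_COLUMNS

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.shape != (len(self.query), 20):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"query length {len(self.query)}"
            )

    def __len__(self) -> int:
        return len(self.query)

    @property
    def normalized(self) -> np.ndarray:
        """(L, 20) matrix of scores squashed to (0,1)."""
        return normalize_pssm(self.scores.astype(float))


def normalize_pssm(x):
    """Squash raw PSSM scores to (0,1) with the logistic 1/(1+e^-x).

    Strictly increasing, so score order is preserved within a column.
    """
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def parse_pssm(path) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` dialect).

    Data rows carry: position, query residue, 20 substitution scores
    (the first score block), then optional percentage/information
    columns which are ignored.
    """
    query: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        lines = fh.readlines()

    started = False
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        if not parts:
            continue
        # header line listing the 20 residue letters (possibly twice)
        if not started:
            if parts[0] == "1" or (len(parts) >= 22 and parts[0].isdigit()):
                started = True
            elif all(len(p) == 1 and p.isalpha() for p in parts) and len(parts) >= 20:
                continue
            else:
                continue
        if started:
            if not parts[0].isdigit():
                break  # footer (lambda/K statistics)
            if len(parts) < 22:
                raise PssmFormatError(
                    f"line {lineno}: expected position, residue and 20 "
                    f"scores, got {len(parts)} fields"
                )
            aa = parts[1]
            if len(aa) != 1 or not aa.isalpha():
                raise PssmFormatError(
                    f"line {lineno}: field 2 is not a residue letter: {aa!r}"
                )
            try:
                scores = [int(v) for v in parts[2:22]]
            except ValueError as exc:
                raise PssmFormatError(
                    f"line {lineno}: non-integer score: {exc}"
                ) from exc
            query.append(aa.upper())
            rows.append(scores)
    if not rows:
        raise PssmFormatError(f"no PSSM data rows found in {path}")
    return PssmProfile(query="".join(query),
                       scores=np.array(rows, dtype=int))


_LN20 = math.log(20.0)


def sequence_entropy(column) -> float | None:
    """Normalized Shannon entropy (0-100) of one alignment column.

    Gaps are excluded from the probabilities; an all-gap column has no
    defined entropy and returns None. 0 means invariant, 100 means all
    20 amino acids equally frequent.
    """
    counts = Counter(
        c.upper() for c in column if c.upper() in AA_ORDER
    )
    total = sum(counts.values())
    if total == 0:
        return None
    h = 0.0
    for n in counts.values():
        p = n / total
        h -= p * math.log(p)
    return 100.0 * h / _LN20


def parse_fasta_msa(path) -> list[str]:
    """Read an aligned FASTA file; returns the aligned sequences.

    All sequences must have equal length (it is an alignment).
    """
    seqs: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
            else:
                current.append(line)
    if current:
        seqs.append("".join(current))
    if not seqs:
        raise ValueError(f"no sequences in FASTA file {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences in {path} are not aligned (lengths {sorted(lengths)})"
        )
    return seqs


def msa_columns(seqs: list[str]):
    """Iterate over alignment columns as strings."""
    for i in range(len(seqs[0])):
        yield "".join(s[i] for s in seqs)


def entropy_to_grades(entropies) -> np.ndarray:
    """Bin per-column entropies into nine within-protein quantile grades,
    inverted so the least entropic (most conserved) columns get grade 9.

    None entries (all-gap columns) get grade 0 (missing).
    """
    ent = np.array([np.nan if e is None else e for e in entropies], float)
    grades = np.zeros(len(ent), dtype=int)
    valid = ~np.isnan(ent)
    if valid.sum() == 0:
        return grades
    vals = ent[valid]
    if np.allclose(vals, vals[0]):
        # no variability to rank: a single invariant level is maximally
        # conserved only if entropy is 0
        grades[valid] = 9 if vals[0] == 0.0 else 5
        return grades
    edges = np.quantile(vals, np.linspace(0, 1, 10)[1:-1])
    binned = np.searchsorted(edges, vals, side="right")  # 0..8, low ent -> 0
    grades[valid] = 9 - binned
    return grades


def parse_consurf_grades(path) -> dict[int, int]:
    """Read a ConSurf-style grades TSV (position, aa, grade).

    Lines starting with '#' are comments. Grades must be integers 1-9.
    """
    grades: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"line {lineno}: expected 'position aa grade', got {line!r}"
                )
            pos, grade = int(parts[0]), int(parts[2])
            if not 1 <= grade <= 9:
                raise ValueError(
                    f"line {lineno}: conservation grade {grade} outside 1-9"
                )
            grades[pos] = grade
    return grades


def conservation_grade(source) -> np.ndarray:
    """Per-position conservation grades (1-9, 9 = conserved).

    ``source`` is either a path to a ConSurf-style grades file or a list
    of aligned sequences (fallback estimator: entropy quantiles).
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        table = parse_consurf_grades(source)
        n = max(table)
        out = np.zeros(n, dtype=int)
        for pos, g in table.items():
            out[pos - 1] = g
        return out
    seqs = list(source)
    ent = [sequence_entropy(col) for col in msa_columns(seqs)]
    return entropy_to_grades(ent)
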