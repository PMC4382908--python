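"""Distance-based training labels from protein coordinates.

Two label families:

* symmetric contacts -- a pair (i, j) is positive when the Cb-Cb
  distance (Ca for glycine) is strictly below a cutoff; an optional
  upper exclusion band marks intermediate-distance pairs as excluded
  so they are skipped during training;
* directed backbone hydrogen bonds -- (i, j) is positive when the amide
  nitrogen of i lies within 3.5 A of the carbonyl oxygen of j and the
  sequence separation is at least 5. No amide hydrogens are rebuilt;
  the heavy-atom distance criterion is used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

HB_DISTANCE = 3.5  # N...O inclusive cutoff, Angstrom
HB_MIN_SEPARATION = 5

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"


@dataclass
class ResidueRecord:
    index: int  # 1-based position in the chain
    aa: str
    CA: np.ndarray | None
    CB: np.ndarray | None
    N: np.ndarray | None
    O: np.ndarray | None
    flagged: bool = False  # missing atoms; excluded from labels touching it

    @property
    def rep(self) -> np.ndarray | None:
        """Contact representative atom: Cb, falling back to Ca for Gly
        (or whenever Cb is absent)."""
        if self.aa != "G" and self.CB is not None:
            return self.CB
        return self.CA


@dataclass
class Structure:
    residues: list[ResidueRecord]
    identifier: str = ""

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if idx != sorted(set(idx)):
            raise ValueError("residue indices must be strictly increasing")

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class ContactLabelSet:
    L: int
    cutoff: float
    exclusion_upper: float | None
    labels: dict[tuple[int, int], str]  # keys i < j, 1-based

    def positives(self) -> set[tuple[int, int]]:
        return {p for p, lab in self.labels.items() if lab == POSITIVE}


@dataclass
class HBondLabelSet:
    L: int
    labels: dict[tuple[int, int], str] = field(default_factory=dict)  # ordered pairs

    def positives(self) -> set[tuple[int, int]]:
        return {p for p, lab in self.labels.items() if lab == POSITIVE}


def parse_coords(path: str | Path, chain: str = "A") -> Structure:
    """Read CA/CB/N/O coordinates for one chain from a PDB file.

    The first model is used; for disordered atoms the first altloc is
    kept. Residues missing CA are flagged.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    model = parser.get_structure(path.stem, str(path))[0]
    if chain not in model:
        raise ValueError(f"{path}: no ATOM records for chain '{chain}'")
    residues = []
    n = 0
    for res in model[chain]:
        if res.id[0] != " ":  # skip HETATM / waters
            continue
        n += 1
        aa = _THREE_TO_ONE.get(res.get_resname(), "X")

        def coord(name: str) -> np.ndarray | None:
            if name not in res:
                return None
            atom = res[name]
            if atom.is_disordered():
                atom = sorted(atom.child_dict.items())[0][1]
            return np.asarray(atom.get_coord(), dtype=float)

        rec = ResidueRecord(
            index=n, aa=aa, CA=coord("CA"), CB=coord("CB"),
            N=coord("N"), O=coord("O"),
        )
        rec.flagged = rec.CA is None
        residues.append(rec)
    if not residues:
        raise ValueError(f"{path}: no ATOM records for chain '{chain}'")
    return Structure(residues, identifier=f"{path.stem}_{chain}")


def contact_labels(
    s: Structure, cutoff: float, exclusion_upper: float | None = None
) -> ContactLabelSet:
    """Label every unordered pair. Positive iff rep-rep distance < cutoff
    (strict); with an exclusion band, cutoff <= d <= exclusion_upper is
    excluded; pairs touching a residue with no representative atom are
    excluded."""
    labels: dict[tuple[int, int], str] = {}
    reps = [r.rep if not r.flagged else None for r in s.residues]
    for a in range(s.L):
        for b in range(a + 1, s.L):
            key = (s.residues[a].index, s.residues[b].index)
            if reps[a] is None or reps[b] is None:
                labels[key] = EXCLUDED
                continue
            d = float(np.linalg.norm(reps[a] - reps[b]))
            if d < cutoff:
                labels[key] = POSITIVE
            elif exclusion_upper is not None and d <= exclusion_upper:
                labels[key] = EXCLUDED
            else:
                labels[key] = NEGATIVE
    return ContactLabelSet(
        L=s.L, cutoff=cutoff, exclusion_upper=exclusion_upper, labels=labels
    )


def hbond_labels(s: Structure) -> HBondLabelSet:
    """Directed backbone hydrogen-bond labels over ordered pairs with
    |i - j| >= 5: (i, j) positive iff N_i ... O_j <= 3.5 A. Both
    orientations are labelled independently (bridged pairs in
    antiparallel sheets may be positive in both directions)."""
    out = HBondLabelSet(L=s.L)
    for donor in s.residues:
        if donor.N is None:
            continue
        for acceptor in s.residues:
            if acceptor.O is None:
                continue
            if abs(donor.index - acceptor.index) < HB_MIN_SEPARATION:
                continue
            d = float(np.linalg.norm(donor.N - acceptor.O))
            out.labels[(donor.index, acceptor.index)] = (
                POSITIVE if d <= HB_DISTANCE else NEGATIVE
            )
    return out


TRAINING_SCHEMES: tuple[tuple[str, float, float | None], ...] = (
    ("6.0", 6.0, None),
    ("7.5", 7.5, None),
    ("8.0", 8.0, None),
    ("8.5", 8.5, None),
    ("10.0", 10.0, None),
    ("8.0/11.0", 8.0, 11.0),
)
"""The six labelling schemes used to train the network ensemble: five
plain distance cutoffs plus an 8 A cutoff whose negatives must exceed
11 A (intermediate pairs excluded from training)."""
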