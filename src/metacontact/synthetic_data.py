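"""Desk-scale synthetic families: toy folds, coupled alignments and
mock secondary-structure / solvent predictions.

The structure generator renders a stylized but geometrically explicit
fold -- an antiparallel beta sheet with a helix packed on top -- chosen
so that the distance-based labelling rules all have non-trivial
instances: helical (i, i+4) N...O hydrogen bonds, symmetric bridged
donor/acceptor pairs across antiparallel strands, and at least L/5
long-range (|i-j| >= 23) contacts between the helix and the sheet.

The alignment simulator evolves rows from the target sequence under
independent drift, except that mutations at structurally contacting
positions co-substitute their partner (with the given coupling
probability) via a compatibility table derived from the packaged
contact potential. Planted contacts thereby become high-MI /
high-coupling column pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from metacontact.alignment_io import AMINO_ACIDS, Alignment, write_a3m, write_psicov
from metacontact.coevolution import ContactPotentialTable, load_contact_potential
from metacontact.structure_labels import (
    HB_DISTANCE,
    HB_MIN_SEPARATION,
    ResidueRecord,
    Structure,
    contact_labels,
)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# strand pools split by which sheet face the backbone N/O point to: the
# hydrogen-bond registry thereby leaves a residue-composition footprint
# (as pleating/packing does in real sheets) that a dedicated head can use
_STRAND_UP_AA = "FYWH"
_STRAND_DOWN_AA = "VILT"
_HELIX_AA = "ALEKMQR"
_LOOP_AA = "GSNDPQ"

STRAND_STEP = 3.5  # A per residue along a strand
STRAND_SPACING = 4.8  # A between adjacent strands
HELIX_RISE = 1.5
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RADIUS = 2.3


@dataclass
class SyntheticFamily:
    structure: Structure
    alignment: Alignment
    planted_contacts: set[tuple[int, int]]
    ss_probs: np.ndarray  # (L, 3) P(H), P(E), P(C)
    solvent: np.ndarray  # (L,)
    seed: int
    identifier: str = ""


def default_fold_spec(L: int) -> list[tuple[str, int]]:
    """Antiparallel sheet (3 strands, 4 from L >= 55) + turns + a helix
    filling the remainder. Requires L >= 30."""
    if L < 30:
        raise ValueError("default fold needs L >= 30")
    n_strands = 4 if L >= 55 else 3
    turn = 3 if L >= 40 else 2
    loop = 2 if L >= 32 else 1
    strand = max(4, min(9, (L - 16) // n_strands))
    used = n_strands * strand + (n_strands - 1) * turn + loop
    helix = L - used
    if helix < 8:
        strand = max(4, strand - (8 - helix + n_strands - 1) // n_strands)
        used = n_strands * strand + (n_strands - 1) * turn + loop
        helix = L - used
    if helix < 8:
        raise ValueError(f"fold spec infeasible for L={L}")
    spec: list[tuple[str, int]] = []
    for k in range(n_strands):
        spec.append(("E", strand))
        if k < n_strands - 1:
            spec.append(("T", turn))
    spec.append(("L", loop))
    spec.append(("H", helix))
    return spec


def _ss_string(fold_spec: list[tuple[str, int]]) -> str:
    out = []
    for kind, n in fold_spec:
        state = {"E": "E", "H": "H"}.get(kind, "C")
        out.append(state * n)
    return "".join(out)


def generate_structure(
    L: int,
    fold_spec: list[tuple[str, int]] | None = None,
    seed: int = 0,
) -> Structure:
    """Render a deterministic toy fold with N, CA, CB and O coordinates.

    Strands lie in the z = 0 plane as a flat antiparallel sheet with N/O
    atoms of adjacent strands pointing at each other (every bridged pair
    is doubly hydrogen bonded); the helix runs along x above the sheet
    with carbonyl oxygens displaced up-axis so that (i, i+4) N...O
    distances fall inside the hydrogen-bond cutoff.

    Which sequential strand occupies which sheet row is a seed-dependent
    permutation, so the strand-pairing pattern -- and hence the
    long-range contact map -- varies between families and cannot be read
    off the secondary structure alone.
    """
    if L < 10:
        raise ValueError("L must be >= 10")
    if fold_spec is None:
        fold_spec = default_fold_spec(L)
    if sum(n for _, n in fold_spec) != L:
        raise ValueError("fold_spec lengths must sum to L")
    # deterministic retry: re-draw the row permutation / helix phase if a
    # marginal arrangement misses the L/5 long-range contact guarantee
    structure = None
    for attempt in range(8):
        structure = _render_fold(L, fold_spec, seed * 131 + attempt)
        pos = contact_labels(structure, 8.0).positives()
        if sum(1 for i, j in pos if j - i >= 23) >= L // 5:
            break
    structure.identifier = f"synth{seed}"
    return structure


def _render_fold(
    L: int, fold_spec: list[tuple[str, int]], render_seed: int
) -> Structure:
    rng = np.random.default_rng(render_seed)
    ss = _ss_string(fold_spec)

    strand_segs = [k for k, (kind, _) in enumerate(fold_spec) if kind == "E"]
    n_strands = len(strand_segs)
    rows = rng.permutation(n_strands) if n_strands > 1 else np.zeros(1, dtype=int)
    row_of = {seg: int(rows[s]) for s, seg in enumerate(strand_segs)}
    helix_len = sum(n for kind, n in fold_spec if kind == "H")
    # the helix runs backwards and ends at x = 0, so its C-terminal turns
    # (long-range in sequence to the first strands) sit above the sheet
    helix_x0 = HELIX_RISE * max(helix_len - 1, 0)
    helix_axis_y = (n_strands - 1) * STRAND_SPACING / 2.0
    helix_axis_z = 6.0

    def seg_start_point(seg_idx: int) -> np.ndarray:
        """Where segment ``seg_idx`` places its first CA."""
        kind, n = fold_spec[seg_idx]
        if kind == "E":
            r = row_of[seg_idx]
            direction = 1 if r % 2 == 0 else -1
            x0 = 0.0 if direction == 1 else (n - 1) * STRAND_STEP
            return np.array([x0, r * STRAND_SPACING, 0.0])
        if kind == "H":
            return np.array([helix_x0, helix_axis_y, helix_axis_z])
        return np.array([0.0, 0.0, 3.0])

    ca = np.zeros((L, 3))
    n_at = np.zeros((L, 3))
    o_at = np.zeros((L, 3))
    cb_dir = np.zeros((L, 3))
    face_up = np.zeros(L, dtype=bool)

    pos = 0
    prev_end: np.ndarray | None = None
    for seg_idx, (kind, seg_len) in enumerate(fold_spec):
        idx = np.arange(pos, pos + seg_len)
        if kind == "E":
            r = row_of[seg_idx]
            direction = 1 if r % 2 == 0 else -1
            x_start = 0.0 if direction == 1 else (seg_len - 1) * STRAND_STEP
            xs = x_start + direction * np.arange(seg_len) * STRAND_STEP
            ca[idx, 0] = xs
            ca[idx, 1] = r * STRAND_SPACING
            # N/O sides alternate with position parity (as in real
            # antiparallel sheets) so both sheet interfaces carry
            # facing, doubly hydrogen-bonded bridge pairs
            for k, t in enumerate(idx):
                x_idx = int(round(xs[k] / STRAND_STEP))
                up = (x_idx + r) % 2 == 0
                side = 0.8 if up else -0.8
                n_at[t] = ca[t] + np.array([-0.6 * direction, side, 0.0])
                o_at[t] = ca[t] + np.array([0.6 * direction, side, 0.0])
                cb_dir[t] = [0.0, 0.0, 1.5 if k % 2 == 0 else -1.5]
                face_up[t] = up
        elif kind == "H":
            theta = HELIX_TWIST * np.arange(seg_len) + rng.uniform(0, 2 * np.pi)
            # run the helix backwards across the sheet so its C-terminal
            # residues -- the ones long-range relative to the first
            # strands -- lie above the sheet for any helix length
            xs = helix_x0 - HELIX_RISE * np.arange(seg_len)
            ca[idx, 0] = xs
            ca[idx, 1] = helix_axis_y + HELIX_RADIUS * np.cos(theta)
            ca[idx, 2] = helix_axis_z + HELIX_RADIUS * np.sin(theta)
            axis = np.array([-1.0, 0.0, 0.0])  # direction of propagation
            radial = ca[idx] - np.stack(
                [xs, np.full(seg_len, helix_axis_y), np.full(seg_len, helix_axis_z)],
                axis=1,
            )
            radial /= np.linalg.norm(radial, axis=1, keepdims=True)
            inward = 0.8  # pull N/O toward the helix axis
            n_at[idx] = ca[idx] - 1.3 * axis - inward * radial
            o_at[idx] = ca[idx] + 2.0 * axis - inward * radial
            cb_dir[idx] = 1.5 * radial
        else:  # turn or loop: arc between the flanking segment endpoints
            start = prev_end if prev_end is not None else np.zeros(3)
            if seg_idx + 1 < len(fold_spec):
                nxt = seg_start_point(seg_idx + 1)
            else:
                nxt = start + np.array([3.0, 0.0, 3.0])
            for k, t in enumerate(idx):
                f = (k + 1) / (seg_len + 1)
                base = (1 - f) * start + f * nxt
                # arc below the sheet plane, clear of the strand N/O plane
                ca[t] = base + np.array([0.0, 0.0, -2.5 * np.sin(np.pi * f)])
            # turns and loops carry no backbone N/O in this stylized
            # geometry: arcs crossing permuted sheet rows would otherwise
            # plant meaningless hydrogen bonds all over the label set
            n_at[idx] = np.nan
            o_at[idx] = np.nan
            cb_dir[idx] = [0.0, 0.0, -1.5]
        prev_end = ca[pos + seg_len - 1].copy()
        pos += seg_len

    seq = _draw_sequence(ss, face_up, rng)
    residues = []
    for t in range(L):
        aa = seq[t]
        cb = None if aa == "G" else ca[t] + cb_dir[t]
        n_t = None if np.isnan(n_at[t]).any() else n_at[t]
        o_t = None if np.isnan(o_at[t]).any() else o_at[t]
        residues.append(
            ResidueRecord(index=t + 1, aa=aa, CA=ca[t], CB=cb, N=n_t, O=o_t)
        )
    return Structure(residues)


def _draw_sequence(ss: str, face_up: np.ndarray, rng: np.random.Generator) -> str:
    out = []
    for t, s in enumerate(ss):
        if s == "E":
            pool = _STRAND_UP_AA if face_up[t] else _STRAND_DOWN_AA
        elif s == "H":
            pool = _HELIX_AA
        else:
            pool = _LOOP_AA
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


# --- alignment simulation --------------------------------------------------


def compatibility_table(
    table: ContactPotentialTable | None = None, temperature: float = 0.15
) -> np.ndarray:
    """(20, 20) row-stochastic matrix: p(partner b | residue a) from
    Boltzmann weights of the packaged contact potential.

    The potential is double-centered first (row/column means removed) so
    the table reflects the pair-specific interaction component; the raw
    matrix is dominated by hydrophobicity, which would make the partner
    choice nearly independent of the conditioning residue.
    """
    table = table or load_contact_potential()
    e = table.e
    centered = e - e.mean(axis=0, keepdims=True) - e.mean(axis=1, keepdims=True) + e.mean()
    w = np.exp(-centered / temperature)
    return w / w.sum(axis=1, keepdims=True)


def planted_contact_pairs(structure: Structure) -> set[tuple[int, int]]:
    """Contact pairs (Cb-Cb < 8 A, separation >= 5) used for coupling."""
    pos = contact_labels(structure, 8.0).positives()
    return {(i, j) for i, j in pos if j - i >= HB_MIN_SEPARATION}


def simulate_msa(
    structure: Structure,
    N: int,
    coupling: float = 0.9,
    mutation_rate: float = 0.7,
    seed: int = 0,
    planted: set[tuple[int, int]] | None = None,
    boosted: set[tuple[int, int]] | None = None,
    boost_coupling: float = 0.95,
    table: ContactPotentialTable | None = None,
) -> Alignment:
    """Evolve N rows from the target sequence on a star phylogeny.

    Row 0 is the unmutated target. Every other row mutates each position
    independently with probability ``mutation_rate`` (uniform draw over
    the 20 residues); afterwards, for every planted contact whose member
    mutated, the partner position is co-substituted with probability
    ``coupling`` from the compatibility table. Pairs in ``boosted``
    (typically hydrogen-bonded bridge pairs, which are geometrically the
    most constrained contacts) co-substitute at ``boost_coupling``
    instead, so they carry a stronger coevolution signal.
    """
    if N < 2:
        raise ValueError("need N >= 2 rows")
    rng = np.random.default_rng(seed)
    comp = compatibility_table(table)
    aa_codes = {a: k for k, a in enumerate(AMINO_ACIDS)}
    ancestor = np.array([aa_codes[a] for a in structure.sequence])
    L = len(ancestor)
    pairs = sorted(planted if planted is not None else planted_contact_pairs(structure))
    boosted = boosted or set()

    rows = [structure.sequence]
    for _ in range(N - 1):
        seq = ancestor.copy()
        mutated = rng.random(L) < mutation_rate
        n_mut = int(mutated.sum())
        if n_mut:
            seq[mutated] = rng.integers(0, 20, size=n_mut)
        for i, j in pairs:
            a, b = i - 1, j - 1
            c = boost_coupling if (i, j) in boosted else coupling
            if mutated[a] and rng.random() < c:
                seq[b] = rng.choice(20, p=comp[seq[a]])
            elif mutated[b] and rng.random() < c:
                seq[a] = rng.choice(20, p=comp[seq[b]])
        rows.append("".join(AMINO_ACIDS[c] for c in seq))
    return Alignment(rows, identifier=structure.identifier)


def simulate_planted_pair_msa(
    L: int,
    N: int,
    coupling: float = 0.9,
    seed: int = 0,
    pair: tuple[int, int] | None = None,
    table: ContactPotentialTable | None = None,
) -> tuple[Alignment, tuple[int, int]]:
    """i.i.d. columns except one strongly coupled pair (1-based).

    Each column draws from its own random 6-residue pool; at the planted
    pair, with probability ``coupling`` the second member is drawn from
    the compatibility table conditioned on the first.
    """
    rng = np.random.default_rng(seed)
    comp = compatibility_table(table)
    if pair is None:
        i0 = int(rng.integers(1, L // 2))
        j0 = int(rng.integers(L // 2 + 1, L + 1))
        pair = (i0, j0)
    pools = [rng.choice(20, size=6, replace=False) for _ in range(L)]
    rows = []
    for _ in range(N):
        seq = np.array([pool[rng.integers(6)] for pool in pools])
        if rng.random() < coupling:
            seq[pair[1] - 1] = rng.choice(20, p=comp[seq[pair[0] - 1]])
        rows.append("".join(AMINO_ACIDS[c] for c in seq))
    return Alignment(rows, identifier=f"planted{seed}"), pair


# --- mock per-residue predictions ------------------------------------------


def true_secondary_structure(structure: Structure) -> str:
    """Recover H/E/C states from geometry: helical (i, i+4) N...O bonds
    mark H; long-range N...O partners mark E; everything else C."""
    L = structure.L
    states = ["C"] * L
    N = [r.N for r in structure.residues]
    O = [r.O for r in structure.residues]

    def bonded(t: int) -> bool:
        if t < 0 or t + 4 >= L or N[t + 4] is None or O[t] is None:
            return False
        return bool(np.linalg.norm(N[t + 4] - O[t]) <= HB_DISTANCE)

    # a lone (t, t+4) bond (e.g. across a hairpin) is not a helix: demand
    # two consecutive helical bonds before assigning H
    for t in range(L - 5):
        if bonded(t) and bonded(t + 1):
            for u in range(t, t + 6):
                states[u] = "H"
    for a in range(L):
        for b in range(L):
            if abs(a - b) >= HB_MIN_SEPARATION and N[a] is not None and O[b] is not None:
                if np.linalg.norm(N[a] - O[b]) <= HB_DISTANCE:
                    if states[a] == "C":
                        states[a] = "E"
                    if states[b] == "C":
                        states[b] = "E"
    # edge-strand residues bond only at alternating positions; close the
    # one-residue gaps so strands come out as contiguous E runs
    for _ in range(2):
        for t in range(1, L - 1):
            if states[t] == "C" and states[t - 1] == "E" and states[t + 1] == "E":
                states[t] = "E"
    return "".join(states)


def mock_predictions(
    structure: Structure, noise: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Mock SS probabilities and solvent exposure from the structure.

    SS probabilities are the true one-hot states blurred with uniform
    confusion ``noise``; solvent exposure is one minus the normalized
    CA-neighbour count within 10 A.
    """
    rng = np.random.default_rng(seed)
    ss = true_secondary_structure(structure)
    L = structure.L
    onehot = np.zeros((L, 3))
    for t, s in enumerate(ss):
        onehot[t, {"H": 0, "E": 1, "C": 2}[s]] = 1.0
    probs = (1 - noise) * onehot + noise / 3.0
    if noise > 0:
        jitter = rng.uniform(0, noise / 10.0, size=(L, 3))
        probs = probs + jitter
    probs /= probs.sum(axis=1, keepdims=True)

    ca = np.stack([r.CA for r in structure.residues])
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    neigh = (d < 10.0).sum(axis=1) - 1
    solvent = 1.0 - neigh / max(neigh.max(), 1)
    return probs, solvent


# --- fixture rendering -----------------------------------------------------


def write_pdb(structure: Structure, path: str | Path, chain: str = "A") -> None:
    serial = 1
    with open(path, "w") as fh:
        for r in structure.residues:
            res3 = _ONE_TO_THREE.get(r.aa, "UNK")
            for name, xyz in (("N", r.N), ("CA", r.CA), ("CB", r.CB), ("O", r.O)):
                if xyz is None:
                    continue
                fh.write(
                    f"ATOM  {serial:5d}  {name:<3s} {res3} {chain}{r.index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"           {name[0]}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


def write_ss2(ss_probs: np.ndarray, sequence: str, path: str | Path) -> None:
    """PSIPRED SS2 layout: idx, aa, state, P(C), P(H), P(E)."""
    states = "HEC"
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (mock)\n\n")
        for t, (row, aa) in enumerate(zip(ss_probs, sequence), 1):
            st = states[int(np.argmax(row))]
            fh.write(
                f"{t:4d} {aa} {st}   {row[2]:5.3f}  {row[0]:5.3f}  {row[1]:5.3f}\n"
            )


def write_solvent(solvent: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t, v in enumerate(solvent, 1):
            fh.write(f"{t:4d} {v:6.4f}\n")


def make_family(
    L: int,
    n_rows: int,
    seed: int,
    coupling: float = 0.9,
    mutation_rate: float = 0.7,
    noise: float = 0.1,
) -> SyntheticFamily:
    """Generate one complete family (structure, MSA, mock predictions)."""
    structure = generate_structure(L, seed=seed)
    planted = planted_contact_pairs(structure)
    aln = simulate_msa(
        structure, n_rows, coupling=coupling, mutation_rate=mutation_rate,
        seed=seed + 1, planted=planted,
    )
    ss_probs, solvent = mock_predictions(structure, noise=noise, seed=seed + 2)
    return SyntheticFamily(
        structure=structure,
        alignment=aln,
        planted_contacts=planted,
        ss_probs=ss_probs,
        solvent=solvent,
        seed=seed,
        identifier=f"fam{seed:04d}",
    )


def build_family_set(
    n_families: int,
    size_range: tuple[int, int] = (40, 80),
    seed: int = 0,
    out_dir: str | Path | None = None,
    rows_range: tuple[int, int] = (100, 500),
    coupling: float = 0.9,
    mutation_rate: float = 0.7,
) -> list[SyntheticFamily]:
    """Generate families and (optionally) render the on-disk fixture
    tree: per-family PDB, PSICOV alignment, A3M, SS2 and solvent files
    plus a manifest of seeds."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    fams = []
    manifest = []
    for k in range(n_families):
        L = int(rng.integers(size_range[0], size_range[1] + 1))
        n_rows = int(rng.integers(rows_range[0], rows_range[1] + 1))
        fam_seed = int(rng.integers(0, 2**31 - 1))
        fam = make_family(L, n_rows, fam_seed, coupling=coupling,
                          mutation_rate=mutation_rate)
        fam.identifier = f"fam{k:04d}"
        fam.structure.identifier = fam.identifier
        fams.append(fam)
        manifest.append(
            {"id": fam.identifier, "L": L, "N": n_rows, "seed": fam_seed,
             "coupling": coupling, "mutation_rate": mutation_rate}
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        for fam in fams:
            d = out_dir / fam.identifier
            d.mkdir(parents=True, exist_ok=True)
            write_pdb(fam.structure, d / f"{fam.identifier}.pdb")
            write_psicov(fam.alignment, d / f"{fam.identifier}.aln")
            write_a3m(fam.alignment, d / f"{fam.identifier}.a3m")
            write_ss2(fam.ss_probs, fam.structure.sequence, d / f"{fam.identifier}.ss2")
            write_solvent(fam.solvent, d / f"{fam.identifier}.solv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return fams
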