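"""Per-column and whole-alignment statistics.

Columns are summarized as 21-bin frequency profiles (20 amino acids plus
gap, the gap counted as a 21st residue type) with a Shannon entropy in
nats. Alignment depth is measured as an effective sequence count N_eff:
rows are clustered by single linkage at a pairwise-identity threshold
(default 62%) and each member of a size-n cluster contributes weight 1/n.

Conventions (fixed here, referenced everywhere else):

* all logarithms are natural;
* ``X`` (unknown) is excluded from both sides of the identity ratio and
  is spread uniformly (1/20 each) over the amino-acid frequency bins, so
  profiles stay 21-dimensional;
* entropy uses 0*log(0) := 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from metacontact.alignment_io import AMINO_ACIDS, GAP, UNKNOWN, Alignment

N_AA = 20
GAP_IDX = 20  # integer code for '-'
UNK_IDX = 21  # integer code for 'X'
N_SYMBOLS = 22

_CODE = {c: i for i, c in enumerate(AMINO_ACIDS)}
_CODE[GAP] = GAP_IDX
_CODE[UNKNOWN] = UNK_IDX


def encode(aln: Alignment) -> np.ndarray:
    """Integer-encode an alignment as an (N, L) uint8 matrix."""
    flat = np.frombuffer("".join(aln.sequences).encode("ascii"), dtype=np.uint8)
    lut = np.full(128, UNK_IDX, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    return lut[flat].reshape(aln.N, aln.L)


@dataclass(frozen=True)
class ColumnProfile:
    """21-bin frequency profile of one alignment column plus its entropy."""

    freqs: np.ndarray  # (21,) -- 20 aa then gap; sums to 1
    entropy: float  # nats, in [0, log 21]

    def __post_init__(self) -> None:
        assert self.freqs.shape == (21,)


@dataclass(frozen=True)
class SequenceWeights:
    """Per-row redundancy weights; neff = sum of weights."""

    weights: np.ndarray  # (N,), each in (0, 1]
    neff: float
    id_threshold: float = 0.62

    @classmethod
    def uniform(cls, n: int) -> "SequenceWeights":
        return cls(weights=np.ones(n), neff=float(n), id_threshold=float("nan"))


@dataclass(frozen=True)
class GlobalAlignmentStats:
    composition: np.ndarray  # (21,) sums to 1
    ss_fractions: np.ndarray  # (3,) H/E/C, sums to 1
    mean_solvent: float
    log_length: float
    log_nseq: float
    log_neff: float
    mean_entropy: float


def _column_counts(codes_col: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted 21-bin counts for one encoded column; X spread 1/20 per aa."""
    counts = np.zeros(21)
    w_sym = np.bincount(codes_col, weights=weights, minlength=N_SYMBOLS)
    counts[:N_AA] = w_sym[:N_AA]
    counts[GAP_IDX] = w_sym[GAP_IDX]
    counts[:N_AA] += w_sym[UNK_IDX] / N_AA
    return counts


def profile_entropy(freqs: np.ndarray) -> float:
    nz = freqs[freqs > 0]
    return float(-np.sum(nz * np.log(nz)))


def column_profile(
    aln: Alignment, col: int, weights: SequenceWeights | None = None
) -> ColumnProfile:
    """Weighted 21-bin frequency profile of 1-based column ``col``."""
    if not 1 <= col <= aln.L:
        raise IndexError(f"column {col} out of range 1..{aln.L}")
    w = weights.weights if weights is not None else np.ones(aln.N)
    codes = encode(aln)[:, col - 1]
    counts = _column_counts(codes, w)
    total = counts.sum()
    freqs = counts / total if total > 0 else counts
    return ColumnProfile(freqs=freqs, entropy=profile_entropy(freqs))


def all_column_profiles(
    aln: Alignment, weights: SequenceWeights | None = None
) -> list[ColumnProfile]:
    """Profiles for every column; one pass over the encoded matrix."""
    w = weights.weights if weights is not None else np.ones(aln.N)
    codes = encode(aln)
    out = []
    for c in range(aln.L):
        counts = _column_counts(codes[:, c], w)
        total = counts.sum()
        freqs = counts / total if total > 0 else counts
        out.append(ColumnProfile(freqs=freqs, entropy=profile_entropy(freqs)))
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions over columns where neither row has
    a gap (or unknown); 0.0 when no comparable columns exist."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    comparable = matches = 0
    for x, y in zip(a, b):
        if x in (GAP, UNKNOWN) or y in (GAP, UNKNOWN):
            continue
        comparable += 1
        if x == y:
            matches += 1
    return matches / comparable if comparable else 0.0


def _identity_links(codes: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """All row pairs (i, j), i<j, with identity >= threshold (vectorized)."""
    valid = codes < N_AA
    n = codes.shape[0]
    links = []
    for i in range(n - 1):
        comp = valid[i] & valid[i + 1 :]
        match = comp & (codes[i] == codes[i + 1 :])
        denom = comp.sum(axis=1)
        num = match.sum(axis=1)
        with np.errstate(invalid="ignore"):
            ident = np.where(denom > 0, num / np.maximum(denom, 1), 0.0)
        for off in np.nonzero(ident >= threshold)[0]:
            links.append((i, i + 1 + int(off)))
    return links


def sequence_weights(aln: Alignment, id_threshold: float = 0.62) -> SequenceWeights:
    """Cluster rows by single linkage at ``id_threshold`` identity and
    weight each member of a size-n cluster 1/n. N_eff = sum of weights,
    i.e. the number of clusters."""
    codes = encode(aln)
    parent = list(range(aln.N))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in _identity_links(codes, id_threshold):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    roots = np.array([find(k) for k in range(aln.N)])
    _, inverse, counts = np.unique(roots, return_inverse=True, return_counts=True)
    weights = 1.0 / counts[inverse]
    return SequenceWeights(
        weights=weights, neff=float(weights.sum()), id_threshold=id_threshold
    )


def global_stats(
    aln: Alignment,
    ss_probs: np.ndarray,
    solvent: np.ndarray,
    weights: SequenceWeights,
) -> GlobalAlignmentStats:
    """Whole-alignment feature block: weighted 21-symbol composition,
    mean predicted SS-state fractions, mean solvent exposure, log sizes
    and mean column entropy."""
    ss_probs = np.asarray(ss_probs, dtype=float)
    solvent = np.asarray(solvent, dtype=float)
    if ss_probs.shape != (aln.L, 3):
        raise ValueError(f"ss_probs must be (L, 3)=({aln.L}, 3), got {ss_probs.shape}")
    if solvent.shape != (aln.L,):
        raise ValueError(f"solvent must have length L={aln.L}, got {solvent.shape}")

    codes = encode(aln)
    comp = np.zeros(21)
    for c in range(aln.L):
        comp += _column_counts(codes[:, c], weights.weights)
    comp /= comp.sum()

    profiles = all_column_profiles(aln, weights)
    mean_entropy = float(np.mean([p.entropy for p in profiles]))
    ss_fractions = ss_probs.mean(axis=0)
    ss_fractions = ss_fractions / ss_fractions.sum()

    return GlobalAlignmentStats(
        composition=comp,
        ss_fractions=ss_fractions,
        mean_solvent=float(solvent.mean()),
        log_length=float(np.log(aln.L)),
        log_nseq=float(np.log(aln.N)),
        log_neff=float(np.log(weights.neff)),
        mean_entropy=mean_entropy,
    )
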