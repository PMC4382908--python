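"""The six pair-score channels derived from an alignment.

Channels (fixed order used downstream):

1. ``MI``        -- mutual information over the 21-symbol alphabet
2. ``nMI``       -- MI normalized by the joint column-pair entropy
3. ``potential`` -- profile-averaged statistical contact potential
4. ``psicov``    -- sparse-coupling slot; built-in stand-in is a
                    shrinkage-regularized inverse covariance score
5. ``mfdca``     -- built-in mean-field direct coupling analysis
6. ``ccmpred``   -- pseudolikelihood slot; built-in stand-in reuses the
                    mean-field estimator with a lighter pseudocount

Slots 4-6 accept externally computed score files (plain "i j score"
lists or dense matrices) in place of the built-in estimators; provenance
is recorded on each matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from metacontact.alignment_io import AMINO_ACIDS, Alignment
from metacontact.profile_stats import (
    GAP_IDX,
    N_AA,
    ColumnProfile,
    SequenceWeights,
    encode,
)

CHANNEL_ORDER = ("MI", "nMI", "potential", "psicov", "mfdca", "ccmpred")

N_STATES = 21  # 20 aa + gap


@dataclass
class PairScoreMatrix:
    scores: np.ndarray  # (L, L), symmetric, zero diagonal
    channel_name: str
    source: str = "built-in"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("pair score matrix must be square")
        if not np.isfinite(s).all():
            raise ValueError("pair score matrix contains non-finite entries")
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("pair score matrix must be symmetric")
        self.scores = s


@dataclass(frozen=True)
class ContactPotentialTable:
    """Published 20x20 statistical pair potential, indexed in the
    alphabetical one-letter order used throughout the package."""

    e: np.ndarray  # (20, 20), symmetric
    provenance: str


def load_contact_potential() -> ContactPotentialTable:
    """Load the packaged Miyazawa-Jernigan style contact energy table."""
    text = (
        resources.files("metacontact")
        .joinpath("data/mj_contact_potential.tsv")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    order = lines[0].split()
    e_file = np.full((20, 20), np.nan)
    for i, line in enumerate(lines[1:]):
        parts = line.split()
        assert parts[0] == order[i]
        vals = [float(v) for v in parts[1:]]
        for off, v in enumerate(vals):
            e_file[i, i + off] = v
            e_file[i + off, i] = v
    perm = [order.index(a) for a in AMINO_ACIDS]
    e = e_file[np.ix_(perm, perm)]
    assert np.isfinite(e).all()
    return ContactPotentialTable(
        e=e, provenance="Miyazawa & Jernigan (1996) J Mol Biol 256:623-644"
    )


# --- weighted one-hot machinery -------------------------------------------


def _onehot(aln: Alignment) -> np.ndarray:
    """(N, L, 21) state indicator; gaps hit bin 20, 'X' spreads 1/20 over
    the amino-acid bins so every row of every position sums to 1."""
    codes = encode(aln)
    lut = np.zeros((22, N_STATES))
    for s in range(N_AA):
        lut[s, s] = 1.0
    lut[GAP_IDX, N_STATES - 1] = 1.0
    lut[21, :N_AA] = 1.0 / N_AA
    return lut[codes]


def _joint_counts(aln: Alignment, weights: SequenceWeights) -> np.ndarray:
    """(L, 21, L, 21) weighted joint frequency tensor, normalized to 1
    per column pair."""
    F = _onehot(aln)
    w = weights.weights / weights.weights.sum()
    Fw = F * w[:, None, None]
    L = aln.L
    flat = F.reshape(aln.N, L * N_STATES)
    flat_w = Fw.reshape(aln.N, L * N_STATES)
    J = flat_w.T @ flat  # (L*21, L*21)
    return J.reshape(L, N_STATES, L, N_STATES)


def _plogp(p: np.ndarray, axis) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t.sum(axis=axis)


def _mi_and_joint_entropy(
    aln: Alignment, weights: SequenceWeights
) -> tuple[np.ndarray, np.ndarray]:
    J = _joint_counts(aln, weights)
    L = aln.L
    # per-column marginals sit on the diagonals of the diagonal blocks
    p_col = np.stack([J[i, :, i, :].diagonal() for i in range(L)])
    H_col = _plogp(p_col, axis=1)  # (L,)
    H_joint = _plogp(J.reshape(L, N_STATES, L, N_STATES), axis=(1, 3))  # (L, L)
    mi = H_col[:, None] + H_col[None, :] - H_joint
    np.fill_diagonal(mi, 0.0)
    mi = np.maximum(0.5 * (mi + mi.T), 0.0)
    return mi, H_joint


def mutual_information(aln: Alignment, weights: SequenceWeights) -> PairScoreMatrix:
    """Weighted mutual information between every pair of columns (nats)."""
    mi, _ = _mi_and_joint_entropy(aln, weights)
    return PairScoreMatrix(mi, "MI")


def normalized_mutual_information(
    aln: Alignment, weights: SequenceWeights
) -> PairScoreMatrix:
    """MI divided by the joint entropy of the column pair; 0 where the
    joint entropy vanishes (both columns constant)."""
    mi, H_joint = _mi_and_joint_entropy(aln, weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        nmi = np.where(H_joint > 1e-12, mi / np.where(H_joint > 1e-12, H_joint, 1.0), 0.0)
    np.fill_diagonal(nmi, 0.0)
    return PairScoreMatrix(0.5 * (nmi + nmi.T), "nMI")


def mean_contact_potential(
    profile_i: ColumnProfile,
    profile_j: ColumnProfile,
    table: ContactPotentialTable,
) -> float:
    """Profile-weighted mean of the pair potential over the two columns.

    Gap frequency is dropped and the amino-acid frequencies renormalized;
    an all-gap column scores 0.
    """
    fi, fj = profile_i.freqs[:N_AA], profile_j.freqs[:N_AA]
    si, sj = fi.sum(), fj.sum()
    if si <= 0 or sj <= 0:
        return 0.0
    return float((fi / si) @ table.e @ (fj / sj))


def potential_matrix(
    profiles: list[ColumnProfile], table: ContactPotentialTable
) -> PairScoreMatrix:
    """L x L mean-contact-potential channel from per-column profiles."""
    F = np.stack([p.freqs[:N_AA] for p in profiles])
    sums = F.sum(axis=1)
    ok = sums > 0
    G = np.zeros_like(F)
    G[ok] = F[ok] / sums[ok, None]
    m = G @ table.e @ G.T
    m[~ok, :] = 0.0
    m[:, ~ok] = 0.0
    np.fill_diagonal(m, 0.0)
    return PairScoreMatrix(m, "potential")


def apc_correct(m: PairScoreMatrix | np.ndarray) -> PairScoreMatrix:
    """Average-product correction: subtract mean_i * mean_j / mean_all,
    means taken over off-diagonal entries. All-zero input is returned
    unchanged."""
    raw = m.scores if isinstance(m, PairScoreMatrix) else np.asarray(m, dtype=float)
    name = m.channel_name if isinstance(m, PairScoreMatrix) else "apc"
    L = raw.shape[0]
    if L < 2 or not np.any(raw):
        return PairScoreMatrix(raw.copy(), name)
    off = ~np.eye(L, dtype=bool)
    row_mean = (raw * off).sum(axis=1) / (L - 1)
    all_mean = raw[off].mean()
    if all_mean == 0:
        return PairScoreMatrix(raw.copy(), name)
    corrected = raw - np.outer(row_mean, row_mean) / all_mean
    np.fill_diagonal(corrected, 0.0)
    return PairScoreMatrix(corrected, name)


# --- coupling estimators ---------------------------------------------------


def _frequencies_with_pseudocount(
    aln: Alignment, weights: SequenceWeights, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single and pair frequencies mixed with a uniform pseudocount."""
    q = N_STATES
    J = _joint_counts(aln, weights)
    L = aln.L
    f1 = np.stack([J[i, :, i, :].diagonal() for i in range(L)])
    lam = pseudocount
    fp1 = lam / q + (1 - lam) * f1
    fp2 = lam / (q * q) + (1 - lam) * J
    for i in range(L):
        fp2[i, :, i, :] = np.diag(fp1[i])
    return fp1, fp2


def mfdca(
    aln: Alignment,
    weights: SequenceWeights,
    pseudocount: float = 0.5,
) -> PairScoreMatrix:
    """Mean-field direct coupling analysis.

    Couplings are estimated as the negative inverse of the pseudocount-
    regularized covariance matrix over 20*L amino-acid states (gap is the
    reference state); the per-pair score is the APC-corrected Frobenius
    norm of each 20x20 coupling block.
    """
    if aln.L < 2 or aln.N < 2:
        raise ValueError("mfdca requires L >= 2 and N >= 2")
    fp1, fp2 = _frequencies_with_pseudocount(aln, weights, pseudocount)
    L, q1 = aln.L, N_AA
    C = fp2[:, :q1, :, :q1] - np.einsum("ia,jb->iajb", fp1[:, :q1], fp1[:, :q1])
    Cm = C.reshape(L * q1, L * q1)
    try:
        Jmat = -np.linalg.inv(Cm)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(
            "covariance matrix is singular; raise the pseudocount"
        ) from exc
    Jt = Jmat.reshape(L, q1, L, q1)
    fro = np.sqrt(np.einsum("iajb,iajb->ij", Jt, Jt))
    np.fill_diagonal(fro, 0.0)
    out = apc_correct(0.5 * (fro + fro.T))
    return PairScoreMatrix(out.scores, "mfdca")


def invcov_scores(
    aln: Alignment,
    weights: SequenceWeights,
    shrinkage: float = 0.1,
) -> PairScoreMatrix:
    """Sparse-coupling stand-in: shrink the 21*L one-hot sample covariance
    toward a scaled identity, invert, and score each pair by the
    APC-corrected L1 norm of its off-diagonal 21x21 precision block."""
    if aln.L < 2 or aln.N < 2:
        raise ValueError("invcov_scores requires L >= 2 and N >= 2")
    if not 0 < shrinkage < 1:
        raise ValueError("shrinkage must be in (0, 1)")
    fp1, fp2 = _frequencies_with_pseudocount(aln, weights, pseudocount=0.2)
    L, q = aln.L, N_STATES
    C = fp2 - np.einsum("ia,jb->iajb", fp1, fp1)
    Cm = C.reshape(L * q, L * q)
    mu = np.trace(Cm) / (L * q)
    Cs = (1 - shrinkage) * Cm + shrinkage * mu * np.eye(L * q)
    try:
        P = np.linalg.inv(Cs)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(
            "shrunk covariance is singular; raise the shrinkage"
        ) from exc
    Pt = P.reshape(L, q, L, q)
    l1 = np.einsum("iajb->ij", np.abs(Pt))
    np.fill_diagonal(l1, 0.0)
    out = apc_correct(0.5 * (l1 + l1.T))
    return PairScoreMatrix(out.scores, "psicov")


# --- external score files --------------------------------------------------


def load_external_scores(
    path: str | Path, L: int, channel_name: str
) -> PairScoreMatrix:
    """Load an externally computed channel.

    Accepts sparse "i j score" lines (1-based indices) or a dense L x L
    matrix (one row per line, CCMpred dialect; symmetrized by averaging).
    Unspecified pairs in the sparse form are 0.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            rows.append((lineno, parts))
    m = np.zeros((L, L))
    if not rows:
        warnings.warn(f"{path}: empty score file; using a zero matrix")
        return PairScoreMatrix(m, channel_name, source="external-file")

    def _looks_sparse() -> bool:
        if not all(len(parts) == 3 for _, parts in rows):
            return False
        # integer-looking first two fields => "i j score" triples
        return all(
            parts[0].lstrip("-").isdigit() and parts[1].lstrip("-").isdigit()
            for _, parts in rows
        )

    if _looks_sparse():
        parsed = _parse_sparse(path, rows, L)
    elif len(rows) == L and all(len(parts) == L for _, parts in rows):
        parsed = _parse_dense(path, rows, L)
    else:
        parsed = _parse_sparse(path, rows, L)
    return PairScoreMatrix(parsed, channel_name, source="external-file")


def _parse_sparse(path: Path, rows, L: int) -> np.ndarray:
    m = np.zeros((L, L))
    for lineno, parts in rows:
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno}: expected 'i j score'")
        try:
            i, j = int(parts[0]), int(parts[1])
            s = float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
        if not (1 <= i <= L and 1 <= j <= L):
            raise ValueError(f"{path}: line {lineno}: index out of range 1..{L}")
        m[i - 1, j - 1] = s
        m[j - 1, i - 1] = s
    np.fill_diagonal(m, 0.0)
    return m


def _parse_dense(path: Path, rows, L: int) -> np.ndarray:
    m = np.zeros((L, L))
    for r, (lineno, parts) in enumerate(rows):
        try:
            m[r] = [float(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


def compute_channels(
    aln: Alignment,
    weights: SequenceWeights,
    profiles: list[ColumnProfile],
    table: ContactPotentialTable | None = None,
    external: dict[str, str | Path] | None = None,
) -> dict[str, PairScoreMatrix]:
    """Assemble all six channels in their fixed order.

    ``external`` may map any of 'psicov', 'mfdca', 'ccmpred' to a score
    file; missing slots fall back to the built-in estimators (psicov ->
    inverse covariance, ccmpred -> mean-field with a lighter pseudocount).
    """
    table = table or load_contact_potential()
    external = external or {}
    channels: dict[str, PairScoreMatrix] = {}
    channels["MI"] = mutual_information(aln, weights)
    channels["nMI"] = normalized_mutual_information(aln, weights)
    channels["potential"] = potential_matrix(profiles, table)
    for name in ("psicov", "mfdca", "ccmpred"):
        if name in external:
            channels[name] = load_external_scores(external[name], aln.L, name)
        elif name == "psicov":
            channels[name] = invcov_scores(aln, weights)
        elif name == "mfdca":
            channels[name] = mfdca(aln, weights)
        else:
            m = mfdca(aln, weights, pseudocount=0.2)
            channels[name] = PairScoreMatrix(m.scores, "ccmpred")
    return channels
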