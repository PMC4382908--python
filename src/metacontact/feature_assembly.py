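"""Assembly of the stage-1 (672) and stage-2 (731) input vectors.

Frozen feature order
--------------------

Stage 1 (672 features)::

    [  0, 243)  9 column blocks (27 each) at i-4 .. i+4
    [243, 486)  9 column blocks at j-4 .. j+4
    [486, 621)  5 column blocks at m-2 .. m+2, m = floor((i+j)/2)
    [621, 627)  pair channels, order (MI, nMI, potential, psicov, mfdca, ccmpred)
    [627, 643)  sequence-separation indicator (16)
    [643, 672)  global block (29): 21 composition, 3 SS fractions,
                mean solvent, log L, log N, log Neff, mean entropy

Stage 2 / 2HB (731 features)::

    [  0, 297)  11 column blocks at i-5 .. i+5
    [297, 594)  11 column blocks at j-5 .. j+5
    [594, 610)  sequence-separation indicator (16); in HB mode the first
                bit flags i > j instead of |i-j| < 5
    [610, 731)  11 x 11 window of the stage-1 score map centred at (i, j),
                row-major; off-map cells 0

A column block (27) is: 21 amino-acid+gap frequencies, P(helix),
P(strand), P(coil), predicted solvent exposure, column entropy, and a
missing-data flag set when the position falls outside the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from metacontact.alignment_io import Alignment
from metacontact.coevolution import (
    CHANNEL_ORDER,
    ContactPotentialTable,
    PairScoreMatrix,
    compute_channels,
)
from metacontact.profile_stats import (
    ColumnProfile,
    GlobalAlignmentStats,
    SequenceWeights,
    all_column_profiles,
    global_stats,
    sequence_weights,
)

COLUMN_BLOCK = 27
SEQSEP_BINS = 16
STAGE1_LEN = 23 * COLUMN_BLOCK + 6 + SEQSEP_BINS + 29  # = 672
STAGE2_LEN = 22 * COLUMN_BLOCK + SEQSEP_BINS + 121  # = 731
MAP_WINDOW = 11

STAGE1_SLICES = {
    "window_i": slice(0, 243),
    "window_j": slice(243, 486),
    "window_mid": slice(486, 621),
    "channels": slice(621, 627),
    "seqsep": slice(627, 643),
    "global": slice(643, 672),
}
STAGE2_SLICES = {
    "window_i": slice(0, 297),
    "window_j": slice(297, 594),
    "seqsep": slice(594, 610),
    "map_window": slice(610, 731),
}


@dataclass
class TargetContext:
    """Everything needed to featurize one target family."""

    aln: Alignment
    weights: SequenceWeights
    profiles: list[ColumnProfile]
    ss_probs: np.ndarray  # (L, 3): P(H), P(E), P(C)
    solvent: np.ndarray  # (L,), 0 buried .. 1 exposed
    channels: dict[str, PairScoreMatrix]  # six, keyed by CHANNEL_ORDER
    stats: GlobalAlignmentStats

    def __post_init__(self) -> None:
        L = self.aln.L
        if len(self.profiles) != L:
            raise ValueError("profiles length != L")
        if self.ss_probs.shape != (L, 3) or self.solvent.shape != (L,):
            raise ValueError("per-residue arrays must have length L")
        if tuple(self.channels) != CHANNEL_ORDER:
            raise ValueError(f"channels must be exactly {CHANNEL_ORDER} in order")
        for m in self.channels.values():
            if m.scores.shape != (L, L):
                raise ValueError("channel matrix size mismatch")

    @property
    def L(self) -> int:
        return self.aln.L


def build_context(
    aln: Alignment,
    ss_probs: np.ndarray,
    solvent: np.ndarray,
    external: dict[str, str | Path] | None = None,
    table: ContactPotentialTable | None = None,
) -> TargetContext:
    """Compute weights, profiles, the six channels and global statistics
    for one alignment."""
    ss_probs = np.asarray(ss_probs, dtype=float)
    solvent = np.asarray(solvent, dtype=float)
    weights = sequence_weights(aln)
    profiles = all_column_profiles(aln, weights)
    channels = compute_channels(aln, weights, profiles, table=table, external=external)
    stats = global_stats(aln, ss_probs, solvent, weights)
    return TargetContext(aln, weights, profiles, ss_probs, solvent, channels, stats)


def seqsep_features(i: int, j: int, hb_mode: bool = False) -> np.ndarray:
    """16-bit sequence-separation code.

    Contact mode: exactly one bit among [<5, =5..=13, 14-17, 18-22,
    23-27, 28-37, 38-47, >=48]. HB mode: the first bit instead flags
    i > j and pairs with separation < 5 are rejected.
    """
    if i == j:
        raise ValueError("i and j must differ")
    sep = abs(i - j)
    v = np.zeros(SEQSEP_BINS)
    if hb_mode:
        if sep < 5:
            raise ValueError("separation < 5 pairs are not presented in HB mode")
        v[0] = 1.0 if i > j else 0.0
    elif sep < 5:
        v[0] = 1.0
        return v
    if 5 <= sep <= 13:
        v[sep - 4] = 1.0
    elif 14 <= sep < 18:
        v[10] = 1.0
    elif 18 <= sep < 23:
        v[11] = 1.0
    elif 23 <= sep < 28:
        v[12] = 1.0
    elif 28 <= sep < 38:
        v[13] = 1.0
    elif 38 <= sep < 48:
        v[14] = 1.0
    else:
        v[15] = 1.0
    return v


def column_block(ctx: TargetContext, pos: int) -> np.ndarray:
    """27-feature description of one alignment column; positions outside
    1..L give all-zero data with the missing flag set."""
    v = np.zeros(COLUMN_BLOCK)
    if pos < 1 or pos > ctx.L:
        v[26] = 1.0
        return v
    p = ctx.profiles[pos - 1]
    v[0:21] = p.freqs
    v[21:24] = ctx.ss_probs[pos - 1]
    v[24] = ctx.solvent[pos - 1]
    v[25] = p.entropy
    return v


def _padded_blocks(ctx: TargetContext, pad: int) -> np.ndarray:
    """(L + 2*pad, 27) block matrix; row k holds the block for 1-based
    position k - pad + 1 (out-of-range rows are missing-flag blocks)."""
    L = ctx.L
    B = np.zeros((L + 2 * pad, COLUMN_BLOCK))
    B[:, 26] = 1.0
    for p in range(1, L + 1):
        B[p - 1 + pad] = column_block(ctx, p)
    return B


def _global_block(ctx: TargetContext) -> np.ndarray:
    g = ctx.stats
    return np.concatenate(
        [
            g.composition,
            g.ss_fractions,
            [g.mean_solvent, g.log_length, g.log_nseq, g.log_neff, g.mean_entropy],
        ]
    )


def _check_pair(ctx: TargetContext, i: int, j: int) -> None:
    if i == j:
        raise ValueError("i and j must differ")
    if not (1 <= i <= ctx.L and 1 <= j <= ctx.L):
        raise ValueError(f"pair ({i}, {j}) out of range 1..{ctx.L}")


def stage1_vector(ctx: TargetContext, i: int, j: int) -> np.ndarray:
    """672-feature first-stage input for the (canonicalized) pair."""
    _check_pair(ctx, i, j)
    return stage1_vectors(ctx, [(i, j)])[0]


def stage1_vectors(ctx: TargetContext, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Batch stage-1 featurization; rows follow ``pairs`` order. Pairs
    are canonicalized to i < j so (i, j) and (j, i) featurize alike."""
    P = np.asarray([(min(i, j), max(i, j)) for i, j in pairs], dtype=int)
    for i, j in P:
        _check_pair(ctx, int(i), int(j))
    pad = 4
    B = _padded_blocks(ctx, pad)
    ii, jj = P[:, 0], P[:, 1]
    mid = (ii + jj) // 2
    off9 = np.arange(-4, 5)
    off5 = np.arange(-2, 3)
    wi = B[(ii[:, None] + off9) - 1 + pad].reshape(len(P), -1)
    wj = B[(jj[:, None] + off9) - 1 + pad].reshape(len(P), -1)
    wm = B[(mid[:, None] + off5) - 1 + pad].reshape(len(P), -1)
    chan = np.stack(
        [ctx.channels[name].scores[ii - 1, jj - 1] for name in CHANNEL_ORDER], axis=1
    )
    seps = np.stack([seqsep_features(int(i), int(j)) for i, j in P])
    glob = np.tile(_global_block(ctx), (len(P), 1))
    out = np.concatenate([wi, wj, wm, chan, seps, glob], axis=1)
    assert out.shape[1] == STAGE1_LEN
    return out


def stage2_vector(
    ctx: TargetContext,
    i: int,
    j: int,
    stage1_map: np.ndarray,
    hb_mode: bool = False,
) -> np.ndarray:
    """731-feature second-stage input: two 11-column windows, the
    separation code, and an 11x11 window of first-stage outputs."""
    _check_pair(ctx, i, j)
    return stage2_vectors(ctx, [(i, j)], stage1_map, hb_mode=hb_mode)[0]


def stage2_vectors(
    ctx: TargetContext,
    pairs: list[tuple[int, int]],
    stage1_map: np.ndarray,
    hb_mode: bool = False,
) -> np.ndarray:
    """Batch stage-2 featurization. In contact mode pairs are
    canonicalized to i < j; in HB mode order is preserved (direction
    matters)."""
    stage1_map = np.asarray(stage1_map, dtype=float)
    if stage1_map.shape != (ctx.L, ctx.L):
        raise ValueError("stage1_map must be (L, L)")
    if stage1_map.min() < -1e-9 or stage1_map.max() > 1 + 1e-9:
        raise ValueError("stage1_map entries must lie in [0, 1]")
    if hb_mode:
        P = np.asarray(pairs, dtype=int)
    else:
        P = np.asarray([(min(i, j), max(i, j)) for i, j in pairs], dtype=int)
    for i, j in P:
        _check_pair(ctx, int(i), int(j))
    pad = 5
    B = _padded_blocks(ctx, pad)
    ii, jj = P[:, 0], P[:, 1]
    off11 = np.arange(-5, 6)
    wi = B[(ii[:, None] + off11) - 1 + pad].reshape(len(P), -1)
    wj = B[(jj[:, None] + off11) - 1 + pad].reshape(len(P), -1)
    seps = np.stack([seqsep_features(int(i), int(j), hb_mode=hb_mode) for i, j in P])
    M = np.zeros((ctx.L + 2 * pad, ctx.L + 2 * pad))
    M[pad : pad + ctx.L, pad : pad + ctx.L] = stage1_map
    r = (ii[:, None] + off11) - 1 + pad
    c = (jj[:, None] + off11) - 1 + pad
    win = M[r[:, :, None], c[:, None, :]].reshape(len(P), -1)
    out = np.concatenate([wi, wj, seps, win], axis=1)
    assert out.shape[1] == STAGE2_LEN
    return out


# --- prediction-file readers ----------------------------------------------


def read_ss2(path: str | Path) -> np.ndarray:
    """Read a PSIPRED SS2-style file into an (L, 3) array ordered
    (P(H), P(E), P(C)). Expected columns: idx, aa, state, P(C), P(H), P(E)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6 or not parts[0].isdigit():
                continue
            pc, ph, pe = (float(x) for x in parts[3:6])
            rows.append((ph, pe, pc))
    if not rows:
        raise ValueError(f"{path}: no SS2 data lines found")
    arr = np.asarray(rows)
    return arr / arr.sum(axis=1, keepdims=True)


def read_solvent(path: str | Path) -> np.ndarray:
    """Read a two-column (idx, exposure) solvent prediction file."""
    vals = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            vals.append(float(parts[-1]))
    if not vals:
        raise ValueError(f"{path}: no solvent data lines found")
    return np.asarray(vals)
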