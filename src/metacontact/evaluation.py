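"""Benchmark machinery: top-L/k precision, redundancy filtering,
consensus ranking and method-overlap counting.

Precision is assessed on ranked pair lists at two sequence-separation
regimes (>= 5 for all-range, >= 23 for long-range) against distance
truth; n = max(1, floor(L * fraction)) predictions are scored. The
redundancy filter greedily drops predictions within Chebyshev distance
1 of an already-kept higher-scoring prediction, so stacks of adjacent
contacts are counted once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from metacontact.coevolution import PairScoreMatrix
from metacontact.structure_labels import ContactLabelSet, HBondLabelSet

Ranked = list[tuple[int, int, float]]  # (i, j, score), sorted non-increasing


def _check_ranked(preds: Ranked) -> None:
    seen = set()
    prev = None
    for i, j, s in preds:
        if (i, j) in seen:
            raise ValueError(f"duplicate pair ({i}, {j})")
        seen.add((i, j))
        if prev is not None and s > prev + 1e-12:
            raise ValueError("predictions must be sorted by non-increasing score")
        prev = s


def rank_pairs(matrix: np.ndarray | PairScoreMatrix, min_sep: int = 1) -> Ranked:
    """Turn a symmetric score matrix into a ranked i<j pair list."""
    m = matrix.scores if isinstance(matrix, PairScoreMatrix) else np.asarray(matrix)
    L = m.shape[0]
    items = [
        (i + 1, j + 1, float(m[i, j]))
        for i in range(L)
        for j in range(i + 1, L)
        if j - i >= min_sep
    ]
    items.sort(key=lambda t: (-t[2], t[0], t[1]))
    return items


def precision_at(
    preds: Ranked,
    truth: ContactLabelSet,
    fraction: float,
    min_sep: int = 5,
) -> float:
    """Precision of the top max(1, floor(L*fraction)) predictions with
    sequence separation >= min_sep."""
    _check_ranked(preds)
    eligible = [(i, j) for i, j, _ in preds if abs(i - j) >= min_sep]
    if not eligible:
        raise ValueError("no predictions at the requested sequence separation")
    n = max(1, int(truth.L * fraction))
    top = eligible[:n]
    positives = truth.positives()
    tp = sum(1 for i, j in top if (min(i, j), max(i, j)) in positives)
    return tp / n


def hbond_precision_at(
    preds: Ranked, truth: HBondLabelSet, fraction: float, min_sep: int = 5
) -> float:
    """Directed-label analogue of :func:`precision_at`: an ordered pair
    (donor, acceptor) only counts when that direction is a true bond."""
    _check_ranked(preds)
    eligible = [(i, j) for i, j, _ in preds if abs(i - j) >= min_sep]
    if not eligible:
        raise ValueError("no predictions at the requested sequence separation")
    n = max(1, int(truth.L * fraction))
    positives = truth.positives()
    tp = sum(1 for p in eligible[:n] if p in positives)
    return tp / n


def redundancy_filter(preds: Ranked) -> Ranked:
    """Greedy top-down filter: keep a prediction iff no already-kept
    prediction lies within Chebyshev distance 1 of it in (i, j) space.
    Removed predictions do not block later ones."""
    _check_ranked(preds)
    kept: Ranked = []
    for i, j, s in preds:
        if all(max(abs(i - ki), abs(j - kj)) > 1 for ki, kj, _ in kept):
            kept.append((i, j, s))
    return kept


def consensus_scores(channels: dict[str, PairScoreMatrix]) -> PairScoreMatrix:
    """Rank-normalized mean of coupling channels: each channel's i<j
    scores are replaced by their normalized ranks (in (0, 1]) before
    averaging, so differently scaled channels contribute equally."""
    mats = list(channels.values())
    L = mats[0].scores.shape[0]
    if any(m.scores.shape != (L, L) for m in mats):
        raise ValueError("all channels must share one size")
    iu = np.triu_indices(L, k=1)
    n = len(iu[0])
    acc = np.zeros(n)
    for m in mats:
        vals = m.scores[iu]
        order = np.argsort(np.argsort(vals, kind="stable"), kind="stable")
        acc += (order + 1) / n
    acc /= len(mats)
    out = np.zeros((L, L))
    out[iu] = acc
    out += out.T
    return PairScoreMatrix(out, "consensus")


def method_overlap(
    preds_by_method: dict[str, Ranked],
    truth: ContactLabelSet,
    k_fraction: float = 0.5,
    min_sep: int = 5,
) -> dict[frozenset[str], int]:
    """Count correct top-L/k predictions per exclusive region of the
    method-intersection (Venn) diagram."""
    if len(preds_by_method) < 2:
        raise ValueError("need at least two methods")
    positives = truth.positives()
    n = max(1, int(truth.L * k_fraction))
    correct_sets: dict[str, set[tuple[int, int]]] = {}
    for name, preds in preds_by_method.items():
        _check_ranked(preds)
        eligible = [(i, j) for i, j, _ in preds if abs(i - j) >= min_sep][:n]
        correct_sets[name] = {
            (min(i, j), max(i, j))
            for i, j in eligible
            if (min(i, j), max(i, j)) in positives
        }
    all_truths = set().union(*correct_sets.values())
    regions: dict[frozenset[str], int] = {}
    for t in all_truths:
        key = frozenset(name for name, cs in correct_sets.items() if t in cs)
        regions[key] = regions.get(key, 0) + 1
    return regions


def evaluate_benchmark(
    targets: list[tuple[Ranked, ContactLabelSet]],
    fractions: tuple[float, ...] = (1.0, 0.5, 0.2, 0.1),
    min_seps: tuple[int, ...] = (5, 23),
    apply_redundancy_filter: bool = False,
) -> dict[tuple[float, int], float]:
    """Mean precision over targets for each (fraction, min_sep) cell."""
    if not targets:
        raise ValueError("need at least one target")
    table: dict[tuple[float, int], float] = {}
    for frac in fractions:
        for sep in min_seps:
            vals = []
            for preds, truth in targets:
                p = redundancy_filter(preds) if apply_redundancy_filter else preds
                vals.append(precision_at(p, truth, frac, min_sep=sep))
            table[(frac, sep)] = float(np.mean(vals))
    return table


def format_benchmark_table(table: dict[tuple[float, int], float]) -> str:
    fractions = sorted({k[0] for k in table}, reverse=True)
    seps = sorted({k[1] for k in table})
    lines = ["min_sep\t" + "\t".join(f"top-L*{f:g}" for f in fractions)]
    for sep in seps:
        lines.append(
            f">={sep}\t" + "\t".join(f"{table[(f, sep)]:.3f}" for f in fractions)
        )
    return "\n".join(lines) + "\n"


def read_casp_rr(path: str | Path) -> Ranked:
    """Read a CASP-RR contact file into a ranked pair list."""
    preds = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 5 and parts[0].isdigit() and parts[1].isdigit():
                preds.append((int(parts[0]), int(parts[1]), float(parts[4])))
    preds.sort(key=lambda t: (-t[2], t[0], t[1]))
    return preds
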