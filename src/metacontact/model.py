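"""Two-stage neural network ensemble, calibration and prediction.

Each classifier is a single-hidden-layer feed-forward network (55
logistic hidden units, one logistic output) trained on cross-entropy by
alternating full-batch ("offline") and per-example stochastic ("online")
epochs, with early stopping on a held-out validation split. Six members
are trained per stage -- one per contact labelling scheme (6, 7.5, 8,
8.5, 10 A cutoffs plus 8 A with an 11 A negative exclusion band) -- and
their outputs are averaged. No class resampling is applied anywhere;
instead, averaged outputs are mapped to estimated positive predictive
values by a fitted log-linear curve PPV = a*log(b*x + c).

The hydrogen-bond head reuses the stage-2 architecture on directed
labels; its six members share one labelling (N...O <= 3.5 A) and differ
by initialization seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from metacontact.feature_assembly import (
    STAGE1_SLICES,
    TargetContext,
    stage1_vectors,
    stage2_vectors,
)
from metacontact.structure_labels import (
    EXCLUDED,
    POSITIVE,
    TRAINING_SCHEMES,
    HB_MIN_SEPARATION,
    Structure,
    contact_labels,
    hbond_labels,
)

N_HIDDEN = 55


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class NetworkWeights:
    W1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float

    @property
    def n_in(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.W1.copy(), self.b1.copy(), self.w2.copy(), self.b2)


@dataclass
class CalibrationParams:
    """PPV = clamp(a * log(b*x + c), 0, 1) with a, b >= 0 and c > 0."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("calibration requires c > 0")
        if self.b < 0 or self.a < 0:
            raise ValueError("calibration requires a >= 0 and b >= 0")


@dataclass
class NetworkEnsemble:
    members: dict[str, NetworkWeights]  # keyed by labelling scheme
    stage: str  # "1", "2" or "2HB"
    calibration: CalibrationParams
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def __post_init__(self) -> None:
        if len(self.members) != 6:
            raise ValueError("ensemble must have exactly 6 member networks")
        n_ins = {m.n_in for m in self.members.values()}
        if len(n_ins) != 1:
            raise ValueError("all members must share one input size")

    @property
    def n_in(self) -> int:
        return next(iter(self.members.values())).n_in


def forward(net: NetworkWeights, x: np.ndarray) -> float:
    """Score a single feature vector; result is in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_in,):
        raise ValueError(f"expected input of length {net.n_in}, got {x.shape}")
    h = _sigmoid(net.W1.T @ x + net.b1)
    return float(_sigmoid(float(net.w2 @ h) + net.b2))


def forward_batch(net: NetworkWeights, X: np.ndarray) -> np.ndarray:
    if X.shape[1] != net.n_in:
        raise ValueError(f"expected inputs of width {net.n_in}, got {X.shape[1]}")
    H = _sigmoid(X @ net.W1 + net.b1)
    return _sigmoid(H @ net.w2 + net.b2)


def _log_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_network(
    features: np.ndarray,
    labels: np.ndarray,
    valid_fraction: float = 0.10,
    seed: int = 0,
    n_hidden: int = N_HIDDEN,
    offline_lr: float = 0.1,
    online_lr: float = 0.01,
    max_rounds: int = 50,
    patience: int = 10,
    valid_mask: np.ndarray | None = None,
    online_batch: int = 1,
) -> NetworkWeights:
    """Train one network with alternating offline/online rounds.

    One round = one full-batch gradient step pass ("offline", learning
    rate offline_lr / n_train) followed by one shuffled stochastic epoch
    ("online"). Training stops when the validation log-loss has not
    improved for ``patience`` rounds; the best-validation weights are
    returned. Deterministic given ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if y.min() == y.max():
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(seed)
    if valid_mask is None:
        n_valid = max(1, int(round(valid_fraction * len(y))))
        order = rng.permutation(len(y))
        valid_mask = np.zeros(len(y), dtype=bool)
        valid_mask[order[:n_valid]] = True
    else:
        valid_mask = np.asarray(valid_mask, dtype=bool)
    Xt, yt = X[~valid_mask], y[~valid_mask]
    Xv, yv = X[valid_mask], y[valid_mask]
    if yt.min() == yt.max():
        raise ValueError("training split must contain both classes")
    n_train, n_in = Xt.shape

    net = NetworkWeights(
        W1=rng.normal(0.0, 1.0 / math.sqrt(n_in), size=(n_in, n_hidden)),
        b1=np.zeros(n_hidden),
        w2=rng.normal(0.0, 1.0 / math.sqrt(n_hidden), size=n_hidden),
        b2=0.0,
    )

    def valid_loss(w: NetworkWeights) -> float:
        return _log_loss(forward_batch(w, Xv), yv)

    best = net.copy()
    best_loss = valid_loss(net)
    since_best = 0
    for _ in range(max_rounds):
        # offline: one full-batch gradient step
        H = _sigmoid(Xt @ net.W1 + net.b1)
        p = _sigmoid(H @ net.w2 + net.b2)
        delta_out = p - yt  # d(loss)/d(z_out), cross-entropy + logistic
        grad_w2 = H.T @ delta_out
        grad_b2 = delta_out.sum()
        delta_h = np.outer(delta_out, net.w2) * H * (1 - H)
        grad_W1 = Xt.T @ delta_h
        grad_b1 = delta_h.sum(axis=0)
        lr = offline_lr / n_train
        net.W1 -= lr * grad_W1
        net.b1 -= lr * grad_b1
        net.w2 -= lr * grad_w2
        net.b2 -= lr * grad_b2

        # online: shuffled stochastic epoch
        order = rng.permutation(n_train)
        for start in range(0, n_train, online_batch):
            idx = order[start : start + online_batch]
            xb, yb = Xt[idx], yt[idx]
            h = _sigmoid(xb @ net.W1 + net.b1)
            pb = _sigmoid(h @ net.w2 + net.b2)
            d_out = (pb - yb) / len(idx)
            d_h = np.outer(d_out, net.w2) * h * (1 - h)
            net.w2 -= online_lr * (h.T @ d_out)
            net.b2 -= online_lr * d_out.sum()
            net.W1 -= online_lr * (xb.T @ d_h)
            net.b1 -= online_lr * d_h.sum(axis=0)

        loss = valid_loss(net)
        if loss < best_loss - 1e-12:
            best_loss, best, since_best = loss, net.copy(), 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    return best


def ensemble_predict(ens: NetworkEnsemble, X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the six member outputs on standardized inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ens.n_in:
        raise ValueError(f"expected inputs of width {ens.n_in}, got {X.shape[1]}")
    Z = (X - ens.feature_mean) / ens.feature_scale
    return np.mean([forward_batch(m, Z) for m in ens.members.values()], axis=0)


# --- calibration -----------------------------------------------------------


def fit_ppv_curve(
    x: np.ndarray,
    ppv: np.ndarray,
    counts: np.ndarray | None = None,
    init: tuple[float, float, float] = (1.0, math.e - 1.0, 1.0),
) -> CalibrationParams:
    """Weighted least-squares fit of PPV = a*log(b*x + c) to observed
    per-bin PPVs (weights = sqrt of bin counts)."""
    x = np.asarray(x, dtype=float)
    ppv = np.asarray(ppv, dtype=float)
    w = np.sqrt(np.asarray(counts, dtype=float)) if counts is not None else np.ones_like(x)

    def resid(theta):
        a, b, c = theta
        return w * (a * np.log(b * x + c) - ppv)

    sol = least_squares(
        resid,
        x0=np.asarray(init, dtype=float),
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    a, b, c = sol.x
    return CalibrationParams(a=float(a), b=float(b), c=float(c))


def fit_ppv_calibration(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 20
) -> CalibrationParams:
    """Bin scores into equal-width bins on [0, 1], measure the observed
    PPV per bin, and fit the log-linear calibration curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges) - 1, 0, n_bins - 1)
    xs, ps, ws = [], [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(scores[mask].mean())
        ps.append(labels[mask].mean())
        ws.append(mask.sum())
    if len(xs) < 2:
        raise ValueError("too few non-empty score bins; reduce n_bins")
    if not (0.0 < np.average(ps, weights=ws) < 1.0):
        raise ValueError("degenerate bins (single class); reduce n_bins")
    return fit_ppv_curve(np.asarray(xs), np.asarray(ps), np.asarray(ws))


def apply_calibration(p: CalibrationParams, x: float | np.ndarray) -> float | np.ndarray:
    """Map raw ensemble scores to estimated PPVs, clamped to [0, 1]."""
    arg = p.b * np.asarray(x, dtype=float) + p.c
    if np.any(arg <= 0):
        raise ValueError("b*x + c must be positive on the score range")
    out = np.clip(p.a * np.log(arg), 0.0, 1.0)
    return float(out) if np.isscalar(x) else out


# --- stage training --------------------------------------------------------


@dataclass
class FamilyData:
    """Featurized training material for one family."""

    ctx: TargetContext
    structure: Structure
    pairs: list[tuple[int, int]]  # all i < j, 1-based
    X1: np.ndarray  # (P, 672)

    @classmethod
    def build(cls, ctx: TargetContext, structure: Structure) -> "FamilyData":
        if ctx.L != structure.L:
            raise ValueError("alignment and structure lengths disagree")
        pairs = [(i, j) for i in range(1, ctx.L + 1) for j in range(i + 1, ctx.L + 1)]
        return cls(ctx, structure, pairs, stage1_vectors(ctx, pairs))


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-9] = 1.0
    return mean, scale


def _family_valid_mask(sizes: list[int], valid_families: set[int]) -> np.ndarray:
    mask = np.zeros(sum(sizes), dtype=bool)
    start = 0
    for k, s in enumerate(sizes):
        if k in valid_families:
            mask[start : start + s] = True
        start += s
    return mask


def _scheme_labels(
    structure: Structure, pairs: list[tuple[int, int]], cutoff: float, excl: float | None
) -> np.ndarray:
    """Per-pair labels: 1 positive, 0 negative, NaN excluded-from-training."""
    ls = contact_labels(structure, cutoff, excl)
    out = np.empty(len(pairs))
    for k, pr in enumerate(pairs):
        lab = ls.labels[pr]
        out[k] = np.nan if lab == EXCLUDED else (1.0 if lab == POSITIVE else 0.0)
    return out


def _train_members(
    X: np.ndarray,
    labels_by_scheme: dict[str, np.ndarray],
    valid_mask: np.ndarray,
    seed: int,
    train_kw: dict,
) -> tuple[dict[str, NetworkWeights], np.ndarray, np.ndarray]:
    mean, scale = _standardize_fit(X)
    Z = (X - mean) / scale
    members: dict[str, NetworkWeights] = {}
    for k, (scheme, y) in enumerate(labels_by_scheme.items()):
        keep = ~np.isnan(y)
        members[scheme] = train_network(
            Z[keep],
            y[keep],
            seed=seed + 1000 * k,
            valid_mask=valid_mask[keep],
            **train_kw,
        )
    return members, mean, scale


def _reference_labels(fams: list[FamilyData]) -> np.ndarray:
    """8 A contact labels over all families, for calibration fitting."""
    return np.concatenate(
        [_scheme_labels(f.structure, f.pairs, 8.0, None) for f in fams]
    )


def train_stage1_ensemble(
    fams: list[FamilyData],
    seed: int = 0,
    zero_channels: bool = False,
    valid_fraction: float = 0.10,
    **train_kw,
) -> NetworkEnsemble:
    """Train the six-member first-stage ensemble on featurized families.

    The validation split holds out whole families (about
    ``valid_fraction`` of them, at least one). ``zero_channels`` trains
    the coevolution-free ablation by zeroing the six channel features.
    """
    X = np.concatenate([f.X1 for f in fams])
    if zero_channels:
        X = X.copy()
        X[:, STAGE1_SLICES["channels"]] = 0.0
    sizes = [len(f.pairs) for f in fams]
    rng = np.random.default_rng(seed)
    n_valid = max(1, int(round(valid_fraction * len(fams))))
    valid_families = set(rng.permutation(len(fams))[:n_valid].tolist())
    valid_mask = _family_valid_mask(sizes, valid_families)

    labels_by_scheme = {
        scheme: np.concatenate(
            [_scheme_labels(f.structure, f.pairs, cutoff, excl) for f in fams]
        )
        for scheme, cutoff, excl in TRAINING_SCHEMES
    }
    members, mean, scale = _train_members(X, labels_by_scheme, valid_mask, seed, train_kw)
    ens = NetworkEnsemble(
        members=members,
        stage="1",
        calibration=CalibrationParams(1.0, math.e - 1.0, 1.0),
        feature_mean=mean,
        feature_scale=scale,
    )
    raw = ensemble_predict(ens, X)
    ref = _reference_labels(fams)
    keep = ~np.isnan(ref)
    ens.calibration = fit_ppv_calibration(raw[keep], ref[keep])
    return ens


def stage1_map(ctx: TargetContext, ens1: NetworkEnsemble, X1: np.ndarray | None = None,
               pairs: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Symmetric (L, L) matrix of raw stage-1 ensemble scores."""
    if pairs is None:
        pairs = [(i, j) for i in range(1, ctx.L + 1) for j in range(i + 1, ctx.L + 1)]
    if X1 is None:
        X1 = stage1_vectors(ctx, pairs)
    raw = ensemble_predict(ens1, X1)
    m = np.zeros((ctx.L, ctx.L))
    for (i, j), s in zip(pairs, raw):
        m[i - 1, j - 1] = m[j - 1, i - 1] = s
    return m


def _crossfit_maps(
    fams: list[FamilyData], folds: int, seed: int, train_kw: dict
) -> list[np.ndarray]:
    """Out-of-fold stage-1 maps: each family's map comes from an
    ensemble trained on the other folds, so the second stage sees maps
    with test-time noise levels instead of overfit training maps."""
    assignment = [k % folds for k in range(len(fams))]
    maps: list[np.ndarray | None] = [None] * len(fams)
    for fold in range(folds):
        held = [k for k, a in enumerate(assignment) if a == fold]
        rest = [f for k, f in enumerate(fams) if assignment[k] != fold]
        ens = train_stage1_ensemble(rest, seed=seed + 7919 * (fold + 1), **train_kw)
        for k in held:
            maps[k] = stage1_map(fams[k].ctx, ens, X1=fams[k].X1, pairs=fams[k].pairs)
    return maps  # type: ignore[return-value]


def train_stage2_ensemble(
    fams: list[FamilyData],
    ens1: NetworkEnsemble,
    seed: int = 0,
    hb: bool = False,
    valid_fraction: float = 0.10,
    crossfit_folds: int = 1,
    **train_kw,
) -> NetworkEnsemble:
    """Train the second-stage (or hydrogen-bond) six-member ensemble.

    Stage-1 maps for the training families are produced by ``ens1``
    directly, or out-of-fold (``crossfit_folds`` > 1) to avoid feeding
    the second stage overfit first-stage maps. In HB mode the six
    members share the single directed labelling and differ by
    initialization; pairs run over both orientations with separation
    >= 5.
    """
    if crossfit_folds > 1:
        train_maps = _crossfit_maps(fams, crossfit_folds, seed, train_kw)
    else:
        train_maps = [
            stage1_map(f.ctx, ens1, X1=f.X1, pairs=f.pairs) for f in fams
        ]
    X_parts, label_parts, sizes = [], [], []
    for f, smap in zip(fams, train_maps):
        if hb:
            hb_pairs = [
                (i, j)
                for i in range(1, f.ctx.L + 1)
                for j in range(1, f.ctx.L + 1)
                if abs(i - j) >= HB_MIN_SEPARATION
            ]
            X_parts.append(stage2_vectors(f.ctx, hb_pairs, smap, hb_mode=True))
            hls = hbond_labels(f.structure)
            label_parts.append(
                np.array(
                    [1.0 if hls.labels.get(p) == POSITIVE else 0.0 for p in hb_pairs]
                )
            )
            sizes.append(len(hb_pairs))
        else:
            X_parts.append(stage2_vectors(f.ctx, f.pairs, smap))
            sizes.append(len(f.pairs))
    X = np.concatenate(X_parts)

    rng = np.random.default_rng(seed)
    n_valid = max(1, int(round(valid_fraction * len(fams))))
    valid_families = set(rng.permutation(len(fams))[:n_valid].tolist())
    valid_mask = _family_valid_mask(sizes, valid_families)

    if hb:
        y_hb = np.concatenate(label_parts)
        labels_by_scheme = {f"hb-init{k}": y_hb for k in range(6)}
    else:
        labels_by_scheme = {
            scheme: np.concatenate(
                [_scheme_labels(f.structure, f.pairs, cutoff, excl) for f in fams]
            )
            for scheme, cutoff, excl in TRAINING_SCHEMES
        }
    members, mean, scale = _train_members(X, labels_by_scheme, valid_mask, seed, train_kw)
    ens = NetworkEnsemble(
        members=members,
        stage="2HB" if hb else "2",
        calibration=CalibrationParams(1.0, math.e - 1.0, 1.0),
        feature_mean=mean,
        feature_scale=scale,
    )
    raw = ensemble_predict(ens, X)
    if hb:
        ref = np.concatenate(label_parts)
        keep = np.ones(len(ref), dtype=bool)
    else:
        ref = _reference_labels(fams)
        keep = ~np.isnan(ref)
    ens.calibration = fit_ppv_calibration(raw[keep], ref[keep])
    return ens


def zero_channel_context(ctx: TargetContext) -> TargetContext:
    """Copy of a context with all six pair channels zeroed, for the
    coevolution-free ("network only") ablation."""
    import copy

    from metacontact.coevolution import PairScoreMatrix

    out = copy.copy(ctx)
    Z = np.zeros((ctx.L, ctx.L))
    out.channels = {name: PairScoreMatrix(Z.copy(), name) for name in ctx.channels}
    return out


# --- prediction ------------------------------------------------------------


@dataclass
class ContactPrediction:
    i: int
    j: int
    raw: float
    ppv: float


@dataclass
class ContactPredictionSet:
    """Scored residue pairs, sorted by calibrated PPV (descending; ties
    broken by smaller i then smaller j)."""

    target: str
    stage: str
    records: list[ContactPrediction] = field(default_factory=list)

    def sort(self) -> None:
        self.records.sort(key=lambda r: (-r.ppv, r.i, r.j))

    def ranked(self) -> list[tuple[int, int, float]]:
        return [(r.i, r.j, r.ppv) for r in self.records]

    def write_casp_rr(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("PFRMAT RR\n")
            fh.write(f"TARGET {self.target}\n")
            fh.write("MODEL 1\n")
            for r in self.records:
                fh.write(f"{r.i} {r.j} 0 8 {r.ppv:.6f}\n")
            fh.write("END\n")

    def write_hbond(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# donor_i acceptor_j ppv\n")
            for r in self.records:
                fh.write(f"{r.i} {r.j} {r.ppv:.6f}\n")


def predict_contacts(
    ctx: TargetContext,
    ens1: NetworkEnsemble,
    ens2: NetworkEnsemble | None = None,
    target: str = "",
) -> ContactPredictionSet:
    """Score all i < j pairs; stage-2 refinement is applied when its
    ensemble is supplied."""
    pairs = [(i, j) for i in range(1, ctx.L + 1) for j in range(i + 1, ctx.L + 1)]
    X1 = stage1_vectors(ctx, pairs)
    raw1 = ensemble_predict(ens1, X1)
    if ens2 is not None:
        if ens2.stage != "2":
            raise ValueError("second ensemble must be stage 2")
        smap = stage1_map(ctx, ens1, X1=X1, pairs=pairs)
        raw = ensemble_predict(ens2, stage2_vectors(ctx, pairs, smap))
        calib = ens2.calibration
        stage = "2"
    else:
        raw, calib, stage = raw1, ens1.calibration, "1"
    ppv = apply_calibration(calib, raw)
    out = ContactPredictionSet(
        target=target or ctx.aln.identifier,
        stage=stage,
        records=[
            ContactPrediction(i, j, float(r), float(p))
            for (i, j), r, p in zip(pairs, raw, ppv)
        ],
    )
    out.sort()
    return out


def predict_hbonds(
    ctx: TargetContext,
    ens1: NetworkEnsemble,
    ens_hb: NetworkEnsemble,
    target: str = "",
) -> ContactPredictionSet:
    """Score all ordered donor/acceptor pairs with separation >= 5;
    (i, j) and (j, i) are distinct records."""
    if ens_hb.stage != "2HB":
        raise ValueError("hydrogen-bond ensemble must be stage 2HB")
    smap = stage1_map(ctx, ens1)
    pairs = [
        (i, j)
        for i in range(1, ctx.L + 1)
        for j in range(1, ctx.L + 1)
        if abs(i - j) >= HB_MIN_SEPARATION
    ]
    raw = ensemble_predict(ens_hb, stage2_vectors(ctx, pairs, smap, hb_mode=True))
    ppv = apply_calibration(ens_hb.calibration, raw)
    out = ContactPredictionSet(
        target=target or ctx.aln.identifier,
        stage="2HB",
        records=[
            ContactPrediction(i, j, float(r), float(p))
            for (i, j), r, p in zip(pairs, raw, ppv)
        ],
    )
    out.sort()
    return out


# --- serialization ---------------------------------------------------------


def save_ensemble(ens: NetworkEnsemble, path: str | Path) -> None:
    """Write a versioned plain-text (JSON) model file."""
    doc = {
        "format": "metacontact-ensemble",
        "version": 1,
        "stage": ens.stage,
        "calibration": {"a": ens.calibration.a, "b": ens.calibration.b, "c": ens.calibration.c},
        "feature_mean": ens.feature_mean.tolist(),
        "feature_scale": ens.feature_scale.tolist(),
        "members": {
            name: {
                "W1": m.W1.tolist(),
                "b1": m.b1.tolist(),
                "w2": m.w2.tolist(),
                "b2": m.b2,
            }
            for name, m in ens.members.items()
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_ensemble(path: str | Path) -> NetworkEnsemble:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "metacontact-ensemble":
        raise ValueError(f"{path}: not a metacontact ensemble file")
    members = {
        name: NetworkWeights(
            W1=np.asarray(m["W1"]),
            b1=np.asarray(m["b1"]),
            w2=np.asarray(m["w2"]),
            b2=float(m["b2"]),
        )
        for name, m in doc["members"].items()
    }
    cal = doc["calibration"]
    return NetworkEnsemble(
        members=members,
        stage=doc["stage"],
        calibration=CalibrationParams(cal["a"], cal["b"], cal["c"]),
        feature_mean=np.asarray(doc["feature_mean"]),
        feature_scale=np.asarray(doc["feature_scale"]),
    )
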