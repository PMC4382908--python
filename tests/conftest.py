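"""Shared fixtures.

The expensive trained-pipeline fixture is session-scoped and shared by
the model tests and the acceptance suite; everything else is cheap and
generated per test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from metacontact.alignment_io import Alignment
from metacontact.feature_assembly import TargetContext, build_context
from metacontact.model import (
    FamilyData,
    NetworkEnsemble,
    train_stage1_ensemble,
    train_stage2_ensemble,
)
from metacontact.synthetic_data import SyntheticFamily, make_family

FAST_TRAIN = dict(max_rounds=12, patience=4, online_batch=8)


def random_alignment(
    rng: np.random.Generator, n: int, length: int, gap_frac: float = 0.1
) -> Alignment:
    alphabet = "ACDEFGHIKLMNPQRSTVWY-"
    probs = np.full(21, (1 - gap_frac) / 20)
    probs[20] = gap_frac
    rows = [
        "".join(rng.choice(list(alphabet), p=probs, size=length)) for _ in range(n)
    ]
    return Alignment(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_family() -> SyntheticFamily:
    """One quick synthetic family (L=40, 80 rows)."""
    return make_family(L=40, n_rows=80, seed=7)


@pytest.fixture(scope="session")
def small_ctx(small_family) -> TargetContext:
    fam = small_family
    return build_context(fam.alignment, fam.ss_probs, fam.solvent)


@dataclass
class TrainedPipeline:
    train: list[FamilyData]
    test: list[tuple[SyntheticFamily, FamilyData]]
    ens1: NetworkEnsemble
    ens2: NetworkEnsemble
    ens1_net_only: NetworkEnsemble
    ens_hb: NetworkEnsemble


@pytest.fixture(scope="session")
def pipeline() -> TrainedPipeline:
    """Train the full two-stage + HB pipeline on 8 synthetic families in
    a weak-coupling regime, holding out 4 for evaluation."""
    fams = []
    for k in range(12):
        fam = make_family(L=60, n_rows=150, seed=k, coupling=0.35)
        ctx = build_context(fam.alignment, fam.ss_probs, fam.solvent)
        fams.append((fam, FamilyData.build(ctx, fam.structure)))
    train = [fd for _, fd in fams[:8]]
    test = fams[8:]
    ens1 = train_stage1_ensemble(train, seed=1, **FAST_TRAIN)
    ens2 = train_stage2_ensemble(
        train, ens1, seed=2, crossfit_folds=2, **FAST_TRAIN
    )
    ens1_net_only = train_stage1_ensemble(
        train, seed=1, zero_channels=True, **FAST_TRAIN
    )
    ens_hb = train_stage2_ensemble(
        train, ens1, seed=3, hb=True, crossfit_folds=2,
        max_rounds=40, patience=12, online_batch=8,
    )
    return TrainedPipeline(train, test, ens1, ens2, ens1_net_only, ens_hb)
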