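"""Class-imbalance balancing for risk datasets.

Three strategies are supported, all operating on rows (not count-weighted
totals): oversampling duplicates every minority-class row to a total
multiplicity ``dup_factor``; down-sampling removes majority-class rows
uniformly at random until ``round(majority_n / reduction_factor)`` remain
(or an explicit target); the mixed strategy does both.  With the published
class sizes (9,305 cancer / 271,355 no-cancer rows) the defaults yield
minority shares of 14.64%, 10.78% and 17.10% respectively.

Duplication copies rows rather than incrementing ``count`` — the ``count``
column is consumed separately as an observation weight during training —
so the two frequency mechanisms stay orthogonal.  ``fold_into_count``
merges the duplicates back afterwards when a compact table is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import BalanceError
from .schema import COUNT_COL, LABEL_COL, RiskDataset


@dataclass
class BalanceSpec:
    strategy: str = "oversample"  # oversample | downsample | mixed
    dup_factor: int = 5
    reduction_factor: float = 3.524
    majority_target: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("oversample", "downsample", "mixed"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.dup_factor < 1:
            raise ValueError("dup_factor must be >= 1")
        if self.reduction_factor < 1:
            raise ValueError("reduction_factor must be >= 1")


#: Fraction of majority rows the mixed strategy retains by default
#: (225,562 of 271,355 in the published balancing table).
MIXED_MAJORITY_FRACTION = 225_562 / 271_355


class ClassShares(NamedTuple):
    majority_n: int
    majority_pct: float
    minor_n: int
    minor_pct: float


def _split_classes(ds: RiskDataset) -> tuple[int, int]:
    """Return (majority_label, minority_label) by row frequency; ties -> 1 minor."""
    labels = ds.df[LABEL_COL]
    n1 = int((labels == 1).sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise BalanceError("dataset contains a single class; cannot balance")
    return (0, 1) if n1 <= n0 else (1, 0)


def class_shares(ds: RiskDataset) -> ClassShares:
    """Row-based class counts and percentages (two decimals)."""
    labels = ds.df[LABEL_COL]
    n1 = int((labels == 1).sum())
    n0 = len(labels) - n1
    total = n0 + n1
    if total == 0:
        raise BalanceError("empty dataset")
    maj_n, min_n = (n0, n1) if n1 <= n0 else (n1, n0)
    return ClassShares(
        majority_n=maj_n,
        majority_pct=round(100.0 * maj_n / total, 2),
        minor_n=min_n,
        minor_pct=round(100.0 * min_n / total, 2),
    )


def oversample(ds: RiskDataset, dup_factor: int = 5) -> RiskDataset:
    """Duplicate every minority row to total multiplicity ``dup_factor``.

    Majority rows are untouched; the original rows keep their order and the
    extra copies are appended, so the operation is deterministic.
    """
    if dup_factor < 1:
        raise ValueError("dup_factor must be >= 1")
    _, minor = _split_classes(ds)
    if dup_factor == 1:
        return RiskDataset(df=ds.df.copy(), schema=ds.schema)
    extra = ds.df[ds.df[LABEL_COL] == minor]
    parts = [ds.df] + [extra] * (dup_factor - 1)
    return RiskDataset(
        df=pd.concat(parts, ignore_index=True), schema=ds.schema
    )


def downsample(
    ds: RiskDataset,
    reduction_factor: float = 3.524,
    seed: int = 0,
    majority_target: int | None = None,
) -> RiskDataset:
    """Remove majority rows uniformly at random, keeping the minority intact.

    ``round(majority_n / reduction_factor)`` rows are retained unless an
    explicit ``majority_target`` overrides the rounding.
    """
    if reduction_factor < 1:
        raise ValueError("reduction_factor must be >= 1")
    major, minor = _split_classes(ds)
    maj_idx = np.flatnonzero((ds.df[LABEL_COL] == major).to_numpy())
    retain = (
        majority_target
        if majority_target is not None
        else int(round(len(maj_idx) / reduction_factor))
    )
    if retain < 1:
        raise BalanceError("reduction leaves zero majority rows")
    if retain > len(maj_idx):
        raise BalanceError(
            f"majority target {retain} exceeds majority size {len(maj_idx)}"
        )
    rng = np.random.default_rng(seed)
    kept = np.sort(rng.choice(maj_idx, size=retain, replace=False))
    min_idx = np.flatnonzero((ds.df[LABEL_COL] == minor).to_numpy())
    sel = np.sort(np.concatenate([kept, min_idx]))
    return RiskDataset(
        df=ds.df.iloc[sel].reset_index(drop=True), schema=ds.schema
    )


def mixed_balance(ds: RiskDataset, spec: BalanceSpec) -> RiskDataset:
    """Oversample the minority and reduce the majority in one pass.

    Without an explicit ``majority_target`` the majority is scaled by
    :data:`MIXED_MAJORITY_FRACTION`.
    """
    over = oversample(ds, spec.dup_factor)
    major, _ = _split_classes(ds)
    maj_n = int((ds.df[LABEL_COL] == major).sum())
    target = (
        spec.majority_target
        if spec.majority_target is not None
        else int(round(maj_n * MIXED_MAJORITY_FRACTION))
    )
    if target == maj_n:
        return over
    return downsample(over, seed=spec.seed, majority_target=target)


def balance(ds: RiskDataset, spec: BalanceSpec) -> RiskDataset:
    """Dispatch to the strategy named in ``spec``."""
    if spec.strategy == "oversample":
        return oversample(ds, spec.dup_factor)
    if spec.strategy == "downsample":
        return downsample(
            ds, spec.reduction_factor, spec.seed, spec.majority_target
        )
    return mixed_balance(ds, spec)


def fold_into_count(ds: RiskDataset) -> RiskDataset:
    """Merge identical rows, summing their ``count`` values."""
    keys = list(ds.factor_names) + [LABEL_COL]
    merged = ds.df.groupby(keys, sort=True)[COUNT_COL].sum().reset_index()
    order = list(ds.factor_names) + [COUNT_COL, LABEL_COL]
    return RiskDataset(df=merged[order], schema=ds.schema)
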