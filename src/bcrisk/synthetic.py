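"""Synthetic BCSC-like dataset generator.

The real BCSC risk-factor file is registration-gated, so every downstream
stage of the pipeline is exercised on synthetic data that reproduces the
published summary statistics: each factor's category marginals, the 3.32% /
96.68% cancer / no-cancer imbalance, and the aggregation of duplicate
factor combinations into a ``count`` column.

Factors are sampled independently from their marginals (only marginals are
published; no joint structure is emulated).  The outcome is a logistic
model in which each factor contributes ``w_i * code / known_max`` — the
code scaled by the factor's largest *known* code so every factor's known
categories span the same [0, 1] range — and the unknown code contributes
zero signal.  The coefficient ``w_i`` is therefore the factor's importance
on a common scale, giving the expert-assigned training weights a
recoverable ground truth: the default coefficients equal the suggested
training weights (1-4) of the weighting stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import CalibrationError
from .schema import (
    COUNT_COL,
    DEFAULT_FACTORS,
    LABEL_COL,
    FactorDef,
    RiskDataset,
)

#: Default per-factor logistic coefficients: the suggested training weights
#: (STW, 1-4) of the weighting stage, applied to code/code_max in [0, 1].
DEFAULT_EFFECT_WEIGHTS: dict[str, float] = {
    "menopaus": 1.0, "agegrp": 4.0, "density": 1.0, "race": 3.0,
    "Hispanic": 1.0, "bmi": 1.0, "agefirst": 2.0, "nrelbc": 3.0,
    "brstproc": 1.0, "lastmamm": 1.0, "surgmeno": 1.0, "hrt": 3.0,
}

#: Published fraction of records labelled cancer (9,305 of 280,660).
DEFAULT_PREVALENCE = 0.0332


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``n_records`` is the number of generated records before duplicate
    aggregation (the sum of counts afterwards).  ``effect_weights`` maps
    factor name to its logistic coefficient on the normalized value; the
    intercept is calibrated so the expected prevalence matches
    ``prevalence``.
    """

    n_records: int = 100_000
    prevalence: float = DEFAULT_PREVALENCE
    seed: int = 0
    effect_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS)
    )
    schema: tuple[FactorDef, ...] = DEFAULT_FACTORS

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        names = {f.name for f in self.schema}
        missing = names - set(self.effect_weights)
        if missing:
            raise ValueError(f"effect_weights missing factors: {sorted(missing)}")


def _calibrate_intercept(linear: np.ndarray, target: float) -> float:
    """Bisect the intercept so mean(expit(b + linear)) == target."""
    lo, hi = -40.0, 40.0
    f = lambda b: float(np.mean(expit(b + linear))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"prevalence {target} unreachable with the given effect weights"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    b = 0.5 * (lo + hi)
    if abs(f(b)) > 0.1 * target:
        raise CalibrationError("intercept calibration did not converge")
    return b


def generate(cfg: SyntheticConfig) -> RiskDataset:
    """Draw a synthetic risk dataset under ``cfg``; deterministic per seed.

    Codes are drawn per factor from the schema marginals; the label is
    Bernoulli with logit = intercept + sum_i w_i * code_i / known_max_i,
    where the factor's unknown code contributes 0.  Identical (codes,
    label) rows are merged with their multiplicities summed into ``count``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_records
    cols = {}
    z = np.zeros((n, len(cfg.schema)))
    for j, fd in enumerate(cfg.schema):
        codes = np.array(fd.codes)
        probs = np.array([fd.marginal[c] for c in fd.codes], dtype=float)
        probs = probs / probs.sum()
        drawn = rng.choice(codes, size=n, p=probs)
        cols[fd.name] = drawn
        contrib = drawn / fd.known_max
        if fd.unknown is not None:
            contrib = np.where(drawn == fd.unknown, 0.0, contrib)
        z[:, j] = contrib

    w = np.array([cfg.effect_weights[fd.name] for fd in cfg.schema])
    linear = z @ w
    intercept = _calibrate_intercept(linear, cfg.prevalence)
    y = rng.binomial(1, expit(intercept + linear)).astype(np.int64)

    df = pd.DataFrame(cols)
    df[LABEL_COL] = y
    grouped = (
        df.groupby(list(df.columns), sort=True).size().reset_index(name=COUNT_COL)
    )
    order = [fd.name for fd in cfg.schema] + [COUNT_COL, LABEL_COL]
    return RiskDataset(df=grouped[order], schema=cfg.schema)


def marginal_report(ds: RiskDataset) -> pd.DataFrame:
    """Count-weighted category percentages per factor.

    Returns a tidy frame with columns ``factor``, ``code``, ``percent``,
    directly comparable to the published dataset description.
    """
    if ds.n_records == 0:
        raise ValueError("empty dataset")
    total = ds.total_count
    rows = []
    for fd in ds.schema:
        shares = ds.df.groupby(fd.name)[COUNT_COL].sum()
        for code, cnt in shares.items():
            rows.append(
                {"factor": fd.name, "code": int(code),
                 "percent": 100.0 * cnt / total}
            )
    return pd.DataFrame(rows)
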