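"""Count-aware prediction tool and full pipeline orchestration.

The prediction tool mirrors the published workflow: a user enters one
individual's 12 factor codes (never a ``count``); the tool looks the
combination up in a reference dataset to recover the record frequency of
that exact combination (1 when unseen), then normalizes and weights the
query exactly as during training and routes it down the fitted tree.

``run_pipeline`` executes the full methodology in its fixed order —
normalize, balance, weight, train, evaluate — from one config, writing the
balanced data, the weight profile, the fitted model and a JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import balancing, synthetic, tree, weighting
from .errors import ConfigError, SchemaError
from .schema import (
    COUNT_COL,
    RiskDataset,
    normalize,
    read_dataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

#: The only admissible stage order.
STAGES = ("normalize", "balance", "weight", "train", "evaluate")


@dataclass
class Query:
    """One individual's factor codes (no count), keyed by factor name."""

    values: dict[str, int]


def lookup_count(q: Query, ref: RiskDataset) -> int:
    """Record frequency of the query's exact factor combination.

    All reference rows matching every one of the 12 codes contribute; their
    ``count`` values are summed (duplicate combinations can occur with
    either outcome label).  An unseen combination has frequency 1.
    """
    names = ref.factor_names
    missing = [n for n in names if n not in q.values]
    if missing:
        raise SchemaError(f"query missing factors: {missing}")
    mask = np.ones(ref.n_records, dtype=bool)
    for name in names:
        mask &= (ref.df[name] == q.values[name]).to_numpy()
    if not mask.any():
        return 1
    return int(ref.df.loc[mask, COUNT_COL].sum())


@dataclass
class RiskModel:
    """A fitted tree bundled with its feature-space construction.

    Stores the per-factor normalization divisors and the weight profile so
    a query can be mapped into exactly the training feature space.
    """

    tree_model: tree.TreeModel
    factors: tuple[str, ...]
    divisors: np.ndarray
    weight_profile: weighting.WeightProfile
    weight_mode: str = "gain-scale"

    def features_from_codes(self, codes: np.ndarray) -> np.ndarray:
        X = np.asarray(codes, dtype=float) / self.divisors
        if self.weight_mode == "column":
            X = X * self.weight_profile.multipliers(self.factors)
        return X

    def save(self, path) -> str:
        payload = {
            "tree": self.tree_model.to_dict(),
            "factors": list(self.factors),
            "divisors": [float(v) for v in self.divisors],
            "stw": {k: int(v) for k, v in self.weight_profile.stw.items()},
            "downscale": {
                k: float(v) for k, v in self.weight_profile.downscale.items()
            },
            "weight_mode": self.weight_mode,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return str(path)

    @classmethod
    def load(cls, path) -> "RiskModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tree_model=tree.TreeModel.from_dict(payload["tree"]),
            factors=tuple(payload["factors"]),
            divisors=np.asarray(payload["divisors"], dtype=float),
            weight_profile=weighting.WeightProfile(
                stw={k: int(v) for k, v in payload["stw"].items()},
                downscale={k: float(v) for k, v in payload["downscale"].items()},
            ),
            weight_mode=payload["weight_mode"],
        )


def train_model(
    ds: RiskDataset,
    wp: weighting.WeightProfile,
    hp: tree.TreeHyperparams | None = None,
    weight_mode: str = "gain-scale",
    divisor_mode: str = "observed-max",
    seed: int = 0,
) -> RiskModel:
    """Normalize, weight and fit a tree on ``ds``; returns the full bundle."""
    nm = normalize(ds, divisor_mode=divisor_mode)
    feats = nm
    fw = None
    if weight_mode == "column":
        feats = weighting.apply_weights(nm, wp)
    else:
        fw = wp.multipliers(nm.factors)
    model = tree.fit_tree(
        feats.values, ds.labels(), ds.counts(),
        hp=hp, weight_mode=weight_mode, feature_weights=fw, seed=seed,
    )
    return RiskModel(
        tree_model=model,
        factors=nm.factors,
        divisors=nm.factor_max,
        weight_profile=wp,
        weight_mode=weight_mode,
    )


def predict_query(
    q: Query, model: RiskModel, ref: RiskDataset | None = None
) -> dict:
    """Score one individual; returns label, class probabilities and count.

    The looked-up count is reported alongside the prediction; the model's
    features are the 12 factors, so the count does not enter tree traversal
    (it is an observation frequency, not a predictor).
    """
    missing = [n for n in model.factors if n not in q.values]
    if missing:
        raise SchemaError(f"query missing factors: {missing}")
    codes = np.array([[q.values[n] for n in model.factors]], dtype=float)
    X = model.features_from_codes(codes)
    label = int(model.tree_model.predict(X)[0])
    proba = model.tree_model.predict_proba(X)[0]
    count = lookup_count(q, ref) if ref is not None else None
    return {
        "label": label,
        "probabilities": {"0": float(proba[0]), "1": float(proba[1])},
        "count": count,
    }


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    ``data`` is either ``{"path": csv}`` or ``{"synthetic": {...}}`` with
    :class:`~bcrisk.synthetic.SyntheticConfig` fields.  ``stages``, when
    given, must equal the canonical order and exists only so a config that
    tries to rearrange the methodology is rejected loudly.
    """

    data: dict = field(default_factory=dict)
    balance: balancing.BalanceSpec = field(default_factory=balancing.BalanceSpec)
    weight_mode: str = "gain-scale"
    downscale: dict[str, float] = field(default_factory=dict)
    hyperparams: tree.TreeHyperparams = field(default_factory=tree.TreeHyperparams)
    folds: int = 5
    divisor_mode: str = "observed-max"
    seed: int = 0
    out_dir: str | None = None
    stages: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.stages is not None and tuple(self.stages) != STAGES:
            raise ConfigError(
                f"stage order must be {STAGES}; got {tuple(self.stages)}"
            )
        if "path" not in self.data and "synthetic" not in self.data:
            raise ConfigError("data must specify 'path' or 'synthetic'")


def run_pipeline(cfg: PipelineConfig) -> tuple[tree.EvalReport, dict]:
    """Run normalize -> balance -> weight -> train -> evaluate.

    Returns the cross-validated evaluation report and an artifacts dict
    (weight profile, fitted model, stage log, report payload).  With
    ``cfg.out_dir`` set, the balanced dataset, weights, model and report
    are also written there.  Deterministic under a fixed seed.
    """
    log: list[str] = []

    def stage(msg):
        log.append(msg)
        logger.info(msg)

    if "path" in cfg.data:
        ds = read_dataset(cfg.data["path"])
        source = str(cfg.data["path"])
    else:
        syn = dict(cfg.data["synthetic"])
        syn.setdefault("seed", cfg.seed)
        scfg = synthetic.SyntheticConfig(**syn)
        ds = synthetic.generate(scfg)
        source = f"synthetic(n={scfg.n_records}, prevalence={scfg.prevalence})"
    stage(f"load: {source} -> {ds.n_records} rows, total count {ds.total_count}")

    # normalization precedes balancing in the methodology; the divisors are
    # computed here and reused after balancing (balancing never adds codes).
    nm = normalize(ds, divisor_mode=cfg.divisor_mode)
    stage(f"normalize: divisors {nm.factor_max.tolist()}")

    balanced = balancing.balance(ds, cfg.balance)
    shares = balancing.class_shares(balanced)
    stage(
        f"balance[{cfg.balance.strategy}]: majority {shares.majority_n} "
        f"({shares.majority_pct}%), minor {shares.minor_n} ({shares.minor_pct}%)"
    )

    profile = weighting.build_doi_profile()
    wp = weighting.stw_map(profile.doi_f)
    wp = weighting.WeightProfile(stw=wp.stw, downscale=dict(cfg.downscale))
    stage(f"weight: stw {wp.stw} downscale {wp.downscale}")

    bnm = normalize(balanced, divisor_mode=cfg.divisor_mode)
    feats = bnm
    fw = None
    if cfg.weight_mode == "column":
        feats = weighting.apply_weights(bnm, wp)
    else:
        fw = wp.multipliers(bnm.factors)
    y, counts = balanced.labels(), balanced.counts()
    report = tree.cross_validate(
        feats.values, y, counts, hp=cfg.hyperparams,
        weight_mode=cfg.weight_mode, feature_weights=fw,
        folds=cfg.folds, seed=cfg.seed,
    )
    stage(
        f"train+evaluate: {report.scheme}, accuracy {report.accuracy:.6f}, "
        f"minor fnr {report.fnr[1]:.6f}"
    )

    model = train_model(
        balanced, wp, hp=cfg.hyperparams, weight_mode=cfg.weight_mode,
        divisor_mode=cfg.divisor_mode, seed=cfg.seed,
    )

    payload = {
        "source": source,
        "balance": {
            "strategy": cfg.balance.strategy,
            "majority_n": shares.majority_n,
            "majority_pct": shares.majority_pct,
            "minor_n": shares.minor_n,
            "minor_pct": shares.minor_pct,
        },
        "weights": {
            "stw": wp.stw,
            "downscale": wp.downscale,
            "mode": cfg.weight_mode,
        },
        "evaluation": report.to_dict(),
        "seed": cfg.seed,
        "stages": log,
    }
    artifacts = {"weight_profile": wp, "model": model, "report": payload}

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(balanced, out / "balanced.csv")
        wp.to_yaml(out / "weights.yaml")
        model.save(out / "model.json")
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        artifacts["out_dir"] = str(out)

    return report, artifacts
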