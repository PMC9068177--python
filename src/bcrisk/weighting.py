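"""Expert-elicited degree-of-importance (DOI) weighting of risk factors.

Two evidence streams are fused into one importance score per risk factor:

* a physician questionnaire summarized as per-factor High / Medium / Low
  risk vote fractions, scored as ``DOI_q = 0.6 * H + 0.4 * M``;
* a tally over four international breast-cancer reports of how many list
  the factor as essential (``Ess``) or secondary (``Sec``), scored as
  ``DOI_r = (0.9 * Ess + 0.1 * Sec) / 4``.

The final importance is the arithmetic mean ``DOI_f = (DOI_q + DOI_r) / 2``
(a factor never mentioned in any report gets ``DOI_r = 0``), and an integer
suggested training weight (STW) in {1, 2, 3, 4} is read off descending
thresholds on ``DOI_f``.  The STW — optionally shrunk by a per-factor
down-scale in (0, 1] for weak-impact factors — multiplies either the
factor's feature column or its split gain during tree induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError, SchemaError
from .schema import FACTOR_NAMES, NormalizedMatrix

#: Default STW thresholds on DOI_f: >= t1 -> 4, >= t2 -> 3, >= t3 -> 2, else 1.
DEFAULT_STW_THRESHOLDS: tuple[float, float, float] = (0.60, 0.44, 0.42)


@dataclass
class QuestionnaireSummary:
    """Per-factor High / Medium / Low vote fractions from the questionnaire."""

    fractions: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for name, (h, m, low) in self.fractions.items():
            for v in (h, m, low):
                if not 0.0 <= v <= 1.0:
                    raise DomainError(
                        f"questionnaire fraction {v} for {name!r} outside [0,1]"
                    )
            if abs(h + m + low - 1.0) > 0.01:
                raise DomainError(
                    f"questionnaire fractions for {name!r} sum to "
                    f"{h + m + low:.4f}, expected 1 +/- 0.01"
                )

    @classmethod
    def from_csv(cls, path) -> "QuestionnaireSummary":
        """Read columns factor, high, medium, low (percent or fraction)."""
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        fr = {}
        for _, row in df.iterrows():
            vals = [float(row[c]) for c in ("high", "medium", "low")]
            if sum(vals) > 1.5:  # given as percentages
                vals = [v / 100.0 for v in vals]
            fr[str(row["factor"])] = tuple(vals)
        return cls(fr)


@dataclass
class ReportTally:
    """Essential / secondary mention counts per factor over ``n`` reports."""

    tallies: dict[str, tuple[int, int]]
    n: int = 4
    denom: float = 4.0

    def __post_init__(self) -> None:
        for name, (ess, sec) in self.tallies.items():
            if ess < 0 or sec < 0 or ess + sec > self.n:
                raise DomainError(
                    f"report tally ({ess}, {sec}) for {name!r} invalid for "
                    f"n={self.n} reports"
                )

    @classmethod
    def from_csv(cls, path, n: int = 4, denom: float = 4.0) -> "ReportTally":
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        tallies = {
            str(r["factor"]): (int(r["essential"]), int(r["secondary"]))
            for _, r in df.iterrows()
        }
        return cls(tallies, n=n, denom=denom)


@dataclass
class DOIProfile:
    """Questionnaire, report and fused DOI per factor, each in [0, 1]."""

    doi_q: dict[str, float]
    doi_r: dict[str, float]
    doi_f: dict[str, float]


@dataclass
class WeightProfile:
    """Integer training weight and optional down-scale per factor."""

    stw: dict[str, int]
    downscale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, w in self.stw.items():
            if w not in (1, 2, 3, 4):
                raise DomainError(f"stw {w} for {name!r} not in {{1,2,3,4}}")
        for name, s in self.downscale.items():
            if not 0.0 < s <= 1.0:
                raise DomainError(f"downscale {s} for {name!r} outside (0,1]")

    def multiplier(self, name: str) -> float:
        return self.stw[name] * self.downscale.get(name, 1.0)

    def multipliers(self, factors) -> np.ndarray:
        missing = [f for f in factors if f not in self.stw]
        if missing:
            raise SchemaError(f"weight profile missing factors: {missing}")
        return np.array([self.multiplier(f) for f in factors])

    def to_yaml(self, path) -> str:
        payload = {
            "stw": {k: int(v) for k, v in self.stw.items()},
            "downscale": {k: float(v) for k, v in self.downscale.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return str(path)

    @classmethod
    def from_yaml(cls, path) -> "WeightProfile":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            stw={k: int(v) for k, v in payload["stw"].items()},
            downscale={k: float(v) for k, v in payload.get("downscale", {}).items()},
        )


# Questionnaire summary: High / Medium / Low vote fractions per factor.
DEFAULT_QUESTIONNAIRE = QuestionnaireSummary(
    {
        "menopaus": (0.300, 0.475, 0.225),
        "agegrp": (0.275, 0.625, 0.100),
        "density": (0.250, 0.450, 0.300),
        "race": (0.250, 0.400, 0.350),
        "Hispanic": (0.194, 0.167, 0.639),
        "bmi": (0.256, 0.385, 0.359),
        "agefirst": (0.275, 0.450, 0.275),
        "nrelbc": (0.564, 0.256, 0.179),
        "brstproc": (0.342, 0.237, 0.421),
        "lastmamm": (0.342, 0.321, 0.337),
        "surgmeno": (0.077, 0.308, 0.615),
        "hrt": (0.425, 0.375, 0.200),
    }
)

# Report tally: (essential, secondary) mentions over the four reports.
# lastmamm is never mentioned, which zero-fills its DOI_r.
DEFAULT_REPORT_TALLY = ReportTally(
    {
        "menopaus": (1, 3),
        "agegrp": (4, 0),
        "density": (2, 2),
        "race": (3, 0),
        "Hispanic": (1, 1),
        "bmi": (1, 3),
        "agefirst": (2, 2),
        "nrelbc": (3, 1),
        "brstproc": (0, 2),
        "lastmamm": (0, 0),
        "surgmeno": (0, 1),
        "hrt": (2, 2),
    }
)


def doi_q(qs: QuestionnaireSummary) -> dict[str, float]:
    """Questionnaire DOI: 0.6 * high + 0.4 * medium, per factor."""
    return {name: 0.6 * h + 0.4 * m for name, (h, m, _) in qs.fractions.items()}


def doi_r(rt: ReportTally) -> dict[str, float]:
    """Report DOI: (0.9 * essential + 0.1 * secondary) / denom, per factor."""
    return {
        name: (0.9 * ess + 0.1 * sec) / rt.denom
        for name, (ess, sec) in rt.tallies.items()
    }


def doi_f(profile_q: dict[str, float], profile_r: dict[str, float]) -> dict[str, float]:
    """Fused DOI: arithmetic mean of the two streams, missing DOI_r -> 0."""
    return {
        name: (q + profile_r.get(name, 0.0)) / 2.0
        for name, q in profile_q.items()
    }


def build_doi_profile(
    qs: QuestionnaireSummary = DEFAULT_QUESTIONNAIRE,
    rt: ReportTally = DEFAULT_REPORT_TALLY,
) -> DOIProfile:
    q = doi_q(qs)
    r = doi_r(rt)
    return DOIProfile(doi_q=q, doi_r=r, doi_f=doi_f(q, r))


def stw_map(
    doi_f_values: dict[str, float],
    thresholds: tuple[float, float, float] = DEFAULT_STW_THRESHOLDS,
) -> WeightProfile:
    """Map fused DOI to integer training weights via descending thresholds."""
    if len(thresholds) != 3 or not all(
        0.0 < t < 1.0 for t in thresholds
    ) or not (thresholds[0] > thresholds[1] > thresholds[2]):
        raise ConfigError(
            f"thresholds must be three strictly descending values in (0,1); "
            f"got {thresholds}"
        )
    t1, t2, t3 = thresholds
    stw = {}
    for name, v in doi_f_values.items():
        if v >= t1:
            stw[name] = 4
        elif v >= t2:
            stw[name] = 3
        elif v >= t3:
            stw[name] = 2
        else:
            stw[name] = 1
    return WeightProfile(stw=stw)


def default_weight_profile() -> WeightProfile:
    """STW profile derived from the bundled questionnaire and report tables."""
    return stw_map(build_doi_profile().doi_f)


def apply_weights(nm: NormalizedMatrix, wp: WeightProfile) -> NormalizedMatrix:
    """Scale each factor column by its stw * downscale multiplier."""
    mult = wp.multipliers(nm.factors)
    return NormalizedMatrix(
        values=nm.values * mult, factor_max=nm.factor_max.copy(),
        factors=nm.factors,
    )


def doi_table(profile: DOIProfile, wp: WeightProfile) -> pd.DataFrame:
    """Summary frame (factor, doi_q, doi_r, doi_f, stw) in schema order."""
    names = [n for n in FACTOR_NAMES if n in profile.doi_f] + [
        n for n in profile.doi_f if n not in FACTOR_NAMES
    ]
    return pd.DataFrame(
        {
            "factor": names,
            "doi_q": [profile.doi_q[n] for n in names],
            "doi_r": [profile.doi_r.get(n, 0.0) for n in names],
            "doi_f": [profile.doi_f[n] for n in names],
            "stw": [wp.stw[n] for n in names],
        }
    )
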