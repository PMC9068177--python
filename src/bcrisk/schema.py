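"""Risk-factor data model for BCSC-style frequency tables.

The Breast Cancer Surveillance Consortium (BCSC) distributes its
risk-factor file as a table of distinct factor-combination rows: 12
categorical risk factors coded as small integers (9 = unknown where
applicable), a binary ``cancer`` outcome, and a ``count`` column holding how
many mammography records share that combination.  This module defines the
schema (factors, legal codes, published marginal percentages), CSV reading
and writing in that dialect, and the per-factor max-normalization that maps
every code into [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateFactorError, ParseError, SchemaError

logger = logging.getLogger(__name__)

COUNT_COL = "count"
LABEL_COL = "cancer"


@dataclass(frozen=True)
class FactorDef:
    """One categorical risk factor: its legal codes and published marginals.

    ``marginal`` maps each code to the percentage of records carrying it in
    the published dataset description; percentages sum to 100 up to the
    rounding of the source table (+/- 0.5).
    """

    name: str
    codes: tuple[int, ...]
    labels: dict[int, str] = field(default_factory=dict)
    marginal: dict[int, float] = field(default_factory=dict)
    #: the code meaning "unknown", where the factor has one (usually 9; the
    #: age-group factor uses 9 as a genuine age band, so it has none)
    unknown: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise SchemaError(f"factor {self.name!r}: duplicate codes")
        if self.unknown is not None and self.unknown not in self.codes:
            raise SchemaError(
                f"factor {self.name!r}: unknown code {self.unknown} not in codes"
            )
        if self.marginal:
            for code, pct in self.marginal.items():
                if not 0.0 <= pct <= 100.0:
                    raise SchemaError(
                        f"factor {self.name!r}: marginal {pct} for code {code} "
                        "outside [0, 100]"
                    )
            total = sum(self.marginal.values())
            if abs(total - 100.0) > 0.5:
                raise SchemaError(
                    f"factor {self.name!r}: marginals sum to {total:.2f}, "
                    "expected 100 +/- 0.5"
                )

    @property
    def code_max(self) -> int:
        return max(self.codes)

    @property
    def known_max(self) -> int:
        """Largest code that is not the unknown code."""
        known = [c for c in self.codes if c != self.unknown]
        return max(known) if known else max(self.codes)


def _f(name, spec, unknown=None):
    """Build a FactorDef from {code: (label, pct)}."""
    return FactorDef(
        name=name,
        codes=tuple(spec),
        labels={c: v[0] for c, v in spec.items()},
        marginal={c: v[1] for c, v in spec.items()},
        unknown=unknown,
    )


#: The 12 BCSC risk factors with their published category percentages.
DEFAULT_FACTORS: tuple[FactorDef, ...] = (
    _f("menopaus", {0: ("pre", 23.47), 1: ("post or age>55", 68.65),
                    9: ("unknown", 7.6)}, unknown=9),
    _f("agegrp", {1: ("35-39", 1.79), 2: ("40-44", 12.1), 3: ("45-49", 16.18),
                  4: ("50-54", 17.9), 5: ("55-59", 13.96), 6: ("60-64", 11.1),
                  7: ("65-69", 9.69), 8: ("70-74", 8.49), 9: ("75-79", 6.06),
                  10: ("80-84", 2.91)}),
    _f("density", {1: ("almost entirely fatty", 6.19),
                   2: ("scattered fibroglandular", 32.69),
                   3: ("heterogeneously dense", 28.17),
                   4: ("extremely dense", 5.68),
                   9: ("unknown or other", 27.26)}, unknown=9),
    _f("race", {1: ("white", 72.63), 2: ("asian/pacific islander", 4.3),
                3: ("black", 5.08), 4: ("native american", 1.19),
                5: ("other/mixed", 0.9), 9: ("unknown", 15.87)}, unknown=9),
    _f("Hispanic", {0: ("no", 73.1), 1: ("yes", 6.58), 9: ("unknown", 20.3)},
       unknown=9),
    _f("bmi", {1: ("10-24.99", 21.27), 2: ("25-29.99", 13.6),
               3: ("30-34.99", 6.05), 4: ("35+", 3.25),
               9: ("unknown", 55.83)}, unknown=9),
    _f("agefirst", {0: ("age<30", 30.18), 1: ("age>=30", 5.9),
                    2: ("nulliparous", 8.41), 9: ("unknown", 55.51)}, unknown=9),
    _f("nrelbc", {0: ("zero", 71.81), 1: ("one", 12.36),
                  2: ("two or more", 0.65), 9: ("unknown", 15.18)}, unknown=9),
    _f("brstproc", {0: ("no", 71.97), 1: ("yes", 17.57),
                    9: ("unknown", 10.46)}, unknown=9),
    _f("lastmamm", {0: ("negative", 75.22), 1: ("false positive", 1.42),
                    9: ("unknown", 23.36)}, unknown=9),
    _f("surgmeno", {0: ("natural", 30.0), 1: ("surgical", 17.86),
                    9: ("unknown or not menopausal", 52.14)}, unknown=9),
    _f("hrt", {0: ("no", 30.47), 1: ("yes", 28.56), 9: ("unknown", 40.97)},
       unknown=9),
)

FACTOR_NAMES: tuple[str, ...] = tuple(f.name for f in DEFAULT_FACTORS)


@dataclass
class RiskDataset:
    """An ordered collection of risk records plus its factor schema.

    ``df`` holds one row per distinct record with the factor columns,
    ``count`` (record frequency, >= 1) and ``cancer`` (0/1).
    """

    df: pd.DataFrame
    schema: tuple[FactorDef, ...] = DEFAULT_FACTORS

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.schema)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def total_count(self) -> int:
        return int(self.df[COUNT_COL].sum())

    def codes(self) -> np.ndarray:
        """Factor codes as an (n_records, n_factors) integer matrix."""
        return self.df[list(self.factor_names)].to_numpy(dtype=np.int64)

    def labels(self) -> np.ndarray:
        return self.df[LABEL_COL].to_numpy(dtype=np.int64)

    def counts(self) -> np.ndarray:
        return self.df[COUNT_COL].to_numpy(dtype=np.int64)

    def validate(self) -> None:
        """Raise SchemaError on any out-of-schema code, count or label."""
        for fd in self.schema:
            bad = ~self.df[fd.name].isin(fd.codes)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"factor {fd.name!r}: illegal code "
                    f"{self.df[fd.name].iloc[row]} at data row {row + 1}"
                )
        if (self.df[COUNT_COL] < 1).any():
            raise SchemaError("count column contains values < 1")
        if ~self.df[LABEL_COL].isin((0, 1)).all():
            raise SchemaError(f"{LABEL_COL} column contains values outside {{0,1}}")


@dataclass
class NormalizedMatrix:
    """Per-record factor values divided by a per-factor maximum.

    ``values`` is (n_records, n_factors) with every entry in [0, 1];
    ``factor_max`` records the divisor actually used per factor.
    """

    values: np.ndarray
    factor_max: np.ndarray
    factors: tuple[str, ...]


def read_dataset(
    path,
    dialect: dict[str, str] | None = None,
    schema: tuple[FactorDef, ...] = DEFAULT_FACTORS,
    mode: str = "strict",
) -> RiskDataset:
    """Read a BCSC-dialect CSV into a :class:`RiskDataset`.

    ``dialect`` maps standard column names (schema factor names, ``count``,
    ``cancer``) to the header names actually present.  A missing ``count``
    column is materialized as 1, the convention for a record never seen in
    the reference file.  In ``strict`` mode a row with an out-of-schema code
    raises :class:`SchemaError`; in ``lenient`` mode such rows are logged
    and dropped.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    dialect = dialect or {}
    rename = {v: k for k, v in dialect.items()}
    raw = raw.rename(columns=rename)

    names = [f.name for f in schema]
    for col in names + [LABEL_COL]:
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
    if COUNT_COL not in raw.columns:
        raw[COUNT_COL] = "1"

    out = {}
    for col in names + [COUNT_COL, LABEL_COL]:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"column {col!r}: non-integer value {raw[col].iloc[row]!r} "
                f"at data row {row + 1}",
                row=row + 1,
            )
        out[col] = numeric.astype(np.int64)
    df = pd.DataFrame(out)

    ds = RiskDataset(df=df, schema=schema)
    if mode == "strict":
        ds.validate()
    else:
        keep = np.ones(len(df), dtype=bool)
        for fd in schema:
            bad = ~df[fd.name].isin(fd.codes).to_numpy()
            if bad.any():
                logger.warning(
                    "dropping %d row(s) with illegal %s codes", bad.sum(), fd.name
                )
                keep &= ~bad
        ds = RiskDataset(df=df[keep].reset_index(drop=True), schema=schema)
    return ds


def write_dataset(ds: RiskDataset, path) -> str:
    """Write ``ds`` to CSV with a fixed column order; round-trips exactly."""
    cols = list(ds.factor_names) + [COUNT_COL, LABEL_COL]
    ds.df.to_csv(path, index=False, columns=cols)
    return str(path)


def normalize(
    ds: RiskDataset,
    divisor_mode: str = "observed-max",
    recode_unknown: bool = False,
) -> NormalizedMatrix:
    """Max-normalize every factor column into [0, 1].

    Each factor value is divided by that factor's maximum: the maximum
    observed in ``ds`` (``observed-max``, the default) or the schema-defined
    maximum code (``code-max``, stable across subsamples).  The unknown code
    9 is normalized like any other numeric category; with
    ``recode_unknown=True`` it is first remapped to the factor's modal known
    code, removing its (usually maximal) numeric influence.
    """
    if divisor_mode not in ("observed-max", "code-max"):
        raise ValueError(f"unknown divisor_mode {divisor_mode!r}")
    mat = ds.codes().astype(np.float64)
    if recode_unknown:
        for j, fd in enumerate(ds.schema):
            if fd.unknown is None:
                continue
            col = mat[:, j]
            known = col[col != fd.unknown]
            if known.size == 0:
                continue
            vals, freq = np.unique(known, return_counts=True)
            col[col == fd.unknown] = vals[np.argmax(freq)]
    if divisor_mode == "observed-max":
        divisors = mat.max(axis=0) if len(mat) else np.zeros(len(ds.schema))
    else:
        divisors = np.array([float(fd.code_max) for fd in ds.schema])
    zero = np.flatnonzero(divisors == 0)
    if zero.size:
        name = ds.schema[zero[0]].name
        raise DegenerateFactorError(
            f"factor {name!r} has maximum 0; cannot normalize"
        )
    return NormalizedMatrix(
        values=mat / divisors, factor_max=divisors, factors=ds.factor_names
    )


def load_schema(path) -> tuple[FactorDef, ...]:
    """Load a factor schema from a YAML file (list of factor mappings)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    factors = []
    for item in spec:
        factors.append(
            FactorDef(
                name=item["name"],
                codes=tuple(int(c) for c in item["codes"]),
                labels={int(k): v for k, v in item.get("labels", {}).items()},
                marginal={int(k): float(v) for k, v in item.get("marginal", {}).items()},
                unknown=item.get("unknown"),
            )
        )
    return tuple(factors)


def dump_schema(schema: tuple[FactorDef, ...], path) -> str:
    """Serialize a factor schema to human-editable YAML."""
    spec = [
        {
            "name": fd.name,
            "codes": list(fd.codes),
            "labels": {int(k): v for k, v in fd.labels.items()},
            "marginal": {int(k): float(v) for k, v in fd.marginal.items()},
            "unknown": fd.unknown,
        }
        for fd in schema
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
    return str(path)
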