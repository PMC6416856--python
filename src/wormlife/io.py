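"""Reading, validation and writing of the tab-separated observation tables.

Six table schemas are supported: ``milestone`` (one worm x timepoint binary
attainment record), ``lifespan`` (death day per worm), ``fecundity`` (embryos
laid per female per adult day), ``lifetable`` (age, l_x, m_x), ``viability``
(plate-level embryo and matured-adult counts) and ``simplemine`` (a WormBase
gene-annotation export, validated only loosely here and parsed in
:mod:`wormlife.phenotypes`).

Column headers are normalized case-insensitively with underscores, and a
small alias map per schema absorbs dialect drift between files. Time is kept
in days internally; hourly observations are converted at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

VALID_TEMPERATURES = {15.0, 20.0, 25.0, 30.0}
MILESTONES = ("hatching", "L4", "young_adult", "reproductive_adult")
REGIMES = ("overnight", "continuous")


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ParseError(ValueError):
    """A cell value violates a schema invariant; carries row locations."""


# canonical column order per schema; (name, required, dtype)
_SCHEMAS: dict[str, list[tuple[str, bool, str]]] = {
    "milestone": [
        ("worm_id", False, "str"),
        ("species", True, "str"),
        ("temperature", True, "float"),
        ("milestone", True, "str"),
        ("time", True, "float"),
        ("status", True, "int"),
    ],
    "lifespan": [
        ("worm_id", False, "str"),
        ("species", True, "str"),
        ("temperature", False, "float"),
        ("day_of_death", True, "int"),
        ("censored", False, "bool"),
    ],
    "fecundity": [
        ("female_id", True, "str"),
        ("species", True, "str"),
        ("temperature", False, "float"),
        ("regime", False, "str"),
        ("day", True, "int"),
        ("count", True, "int"),
    ],
    "lifetable": [
        ("species", False, "str"),
        ("regime", False, "str"),
        ("age", True, "int"),
        ("l_x", True, "float"),
        ("m_x", True, "float"),
    ],
    "viability": [
        ("plate_id", True, "str"),
        ("species", True, "str"),
        ("temperature", True, "float"),
        ("embryos_initial", True, "int"),
        ("matured", True, "int"),
    ],
}

_ALIASES: dict[str, dict[str, str]] = {
    "milestone": {
        "stage": "milestone",
        "event": "milestone",
        "time_days": "time",
        "temp": "temperature",
        "strain": "species",
        "developmental_status": "status",
    },
    "lifespan": {
        "death_day": "day_of_death",
        "days_alive": "day_of_death",
        "total_lifespan": "day_of_death",
        "temp": "temperature",
        "strain": "species",
    },
    "fecundity": {
        "embryos": "count",
        "offspring": "count",
        "brood": "count",
        "adult_day": "day",
        "worm_id": "female_id",
        "id": "female_id",
        "temp": "temperature",
        "strain": "species",
        "mating": "regime",
    },
    "lifetable": {"x": "age", "lx": "l_x", "mx": "m_x", "day": "age"},
    "viability": {
        "plate": "plate_id",
        "embryos": "embryos_initial",
        "initial_embryos": "embryos_initial",
        "n_embryos": "embryos_initial",
        "adults": "matured",
        "mature_worms": "matured",
        "n_adults": "matured",
        "temp": "temperature",
        "strain": "species",
    },
    "simplemine": {},
}


@dataclass
class Dataset:
    """A validated observation table plus provenance.

    ``df`` holds one row per record with canonical column names; extra
    metadata columns from the source file are preserved verbatim after the
    canonical ones.
    """

    df: pd.DataFrame
    schema: str
    source_file: Path | None = None
    n_dropped: int = 0
    notes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other: "Dataset") -> bool:
        return self.schema == other.schema and self.df.reset_index(
            drop=True
        ).equals(other.df.reset_index(drop=True))


def _normalize(name: str) -> str:
    out = name.strip().lower().replace(" ", "_").replace("-", "_")
    # keep the milestone stage column "L4" capitalization irrelevant
    return out


def _canonicalize_columns(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    aliases = _ALIASES.get(schema, {})
    mapping = {}
    for col in df.columns:
        norm = _normalize(str(col))
        mapping[col] = aliases.get(norm, norm)
    out = df.rename(columns=mapping)
    if out.columns.duplicated().any():
        dupes = out.columns[out.columns.duplicated()].tolist()
        raise SchemaError(f"duplicate columns after normalization: {dupes}")
    return out


def _coerce(df: pd.DataFrame, col: str, dtype: str) -> pd.Series:
    s = df[col]
    try:
        if dtype == "float":
            return pd.to_numeric(s, errors="raise").astype(float)
        if dtype == "int":
            num = pd.to_numeric(s, errors="raise")
            if (num % 1 != 0).any():
                bad = df.index[num % 1 != 0][:5].tolist()
                raise ParseError(
                    f"column {col!r} must be integer; fractional values at "
                    f"rows {bad}"
                )
            return num.astype(int)
        if dtype == "bool":
            if s.dtype == bool:
                return s
            lowered = s.astype(str).str.strip().str.lower()
            mapping = {
                "true": True, "false": False, "1": True, "0": False,
                "yes": True, "no": False,
            }
            if not lowered.isin(mapping).all():
                bad = df.index[~lowered.isin(mapping)][:5].tolist()
                raise ParseError(f"column {col!r} not boolean at rows {bad}")
            return lowered.map(mapping)
        return s.astype(str)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"non-numeric value in column {col!r}: {exc}") from exc


def _check(condition: pd.Series, message: str) -> None:
    if not condition.all():
        rows = condition.index[~condition][:10].tolist()
        raise ParseError(f"{message} (rows {rows})")


def _validate(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    spec = _SCHEMAS[schema]
    for name, required, _ in spec:
        if required and name not in df.columns:
            raise SchemaError(f"schema {schema!r} requires column {name!r}")
    for name, _, dtype in spec:
        if name in df.columns:
            df[name] = _coerce(df, name, dtype)
    for col in df.columns:
        if df[col].isna().any():
            rows = df.index[df[col].isna()][:10].tolist()
            raise ParseError(f"missing values in column {col!r} (rows {rows})")

    if "temperature" in df.columns:
        _check(
            df["temperature"].isin(VALID_TEMPERATURES),
            "temperature must be one of 15, 20, 25, 30 °C",
        )
    if schema == "milestone":
        _check(df["status"].isin([0, 1]), "status must be 0 or 1")
        _check(df["time"] >= 0, "time must be >= 0")
        _check(df["milestone"].isin(MILESTONES),
               f"milestone must be one of {MILESTONES}")
    elif schema == "lifespan":
        _check(df["day_of_death"] >= 1, "day_of_death must be >= 1")
        if "censored" not in df.columns:
            df["censored"] = False
    elif schema == "fecundity":
        _check(df["count"] >= 0, "daily embryo count must be >= 0")
        _check(df["day"] >= 1, "adult day must be >= 1")
        if "regime" in df.columns:
            _check(df["regime"].isin(REGIMES),
                   f"regime must be one of {REGIMES}")
    elif schema == "lifetable":
        _check((df["l_x"] >= 0) & (df["l_x"] <= 1), "l_x must lie in [0, 1]")
        _check(df["m_x"] >= 0, "m_x must be >= 0")
        _check(df["age"] >= 0, "age must be >= 0")
        group_cols = [c for c in ("species", "regime") if c in df.columns]
        grouped = df.groupby(group_cols, sort=False) if group_cols else [(None, df)]
        for _, sub in grouped:
            sub = sub.sort_values("age")
            if sub["age"].duplicated().any():
                raise ParseError("duplicate ages within a life table group")
            if not sub["l_x"].is_monotonic_decreasing:
                raise ParseError("l_x must be nonincreasing with age")
            if sub["age"].iloc[0] == 0 and sub["l_x"].iloc[0] != 1.0:
                raise ParseError("l_x at age 0 must equal 1")
    elif schema == "viability":
        _check(df["embryos_initial"] > 0, "embryos_initial must be > 0")
        _check(df["matured"] >= 0, "matured must be >= 0")
        _check(df["matured"] <= df["embryos_initial"],
               "matured cannot exceed embryos_initial")
    return df


def read_table(
    path: str | Path,
    schema: str,
    time_unit: str = "days",
    drop_never_attained: bool = True,
) -> Dataset:
    """Read and validate a tab-separated observation table.

    Parameters
    ----------
    path : path to a TSV file with a header row.
    schema : one of {"milestone", "lifespan", "fecundity", "lifetable",
        "viability", "simplemine"}.
    time_unit : {"days", "hours"}
        Unit of the ``time`` column for milestone tables. Hourly hatching
        observations are converted to days (hours/24) on read.
    drop_never_attained : bool
        For milestone tables with a ``worm_id`` column, drop worms that never
        reached the milestone during the assay (they carry no information on
        attainment time). The number dropped is logged and recorded on the
        Dataset.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ParseError
        If a cell violates an invariant; the message carries row numbers.
    """
    path = Path(path)
    if schema not in set(_SCHEMAS) | {"simplemine"}:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str if schema == "simplemine" else None)
    df = _canonicalize_columns(df, schema)

    if schema == "simplemine":
        if df.shape[1] < 2:
            raise SchemaError(
                "simplemine export needs a gene column and at least one "
                "phenotype column"
            )
        return Dataset(df=df, schema=schema, source_file=path)

    df = _validate(df, schema)

    notes: list[str] = []
    n_dropped = 0
    if schema == "milestone" and time_unit == "hours":
        df["time"] = df["time"] / 24.0
        notes.append("time converted from hours to days")
    elif time_unit not in ("days", "hours"):
        raise ValueError("time_unit must be 'days' or 'hours'")

    if schema == "milestone" and drop_never_attained and "worm_id" in df.columns:
        keys = ["worm_id", "species", "milestone"]
        attained = df.groupby(keys, sort=False)["status"].transform("max")
        n_dropped = df.loc[attained == 0].groupby(keys, sort=False).ngroups
        df = df[attained == 1].reset_index(drop=True)
        if n_dropped:
            msg = f"dropped {n_dropped} worms that never attained the milestone"
            logger.info(msg)
            notes.append(msg)

    # canonical column order, extras preserved after
    order = [c for c, _, _ in _SCHEMAS[schema] if c in df.columns]
    extras = [c for c in df.columns if c not in order]
    df = df[order + extras].reset_index(drop=True)
    return Dataset(df=df, schema=schema, source_file=path,
                   n_dropped=n_dropped, notes=notes)


def write_table(data: Dataset, path: str | Path) -> Path:
    """Write a Dataset back to TSV, byte-stable for fixed input.

    Column order follows the schema canon (extras last), newline is ``\\n``.
    """
    path = Path(path)
    data.df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def from_frame(df: pd.DataFrame, schema: str) -> Dataset:
    """Validate an in-memory DataFrame into a Dataset (no file involved)."""
    df = _canonicalize_columns(df.copy(), schema)
    if schema != "simplemine":
        df = _validate(df, schema)
        order = [c for c, _, _ in _SCHEMAS[schema] if c in df.columns]
        extras = [c for c in df.columns if c not in order]
        df = df[order + extras].reset_index(drop=True)
    return Dataset(df=df, schema=schema)


def concat(datasets: Iterable[Dataset]) -> Dataset:
    datasets = list(datasets)
    schemas = {d.schema for d in datasets}
    if len(schemas) != 1:
        raise ValueError(f"cannot concatenate mixed schemas {schemas}")
    df = pd.concat([d.df for d in datasets], ignore_index=True)
    return Dataset(df=df, schema=schemas.pop())
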