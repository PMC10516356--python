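"""Survey micro-data: reading, validation, and the fractional-rank SES score.

The central in-memory container is :class:`SurveyTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per respondent.  Parental
education is recorded on one ordered categorical scale for mother and
father separately; :func:`resolve_household_education` collapses the two
to the household maximum, and :func:`ses_rank` converts the ordinal
categories into a within-country fractional rank in ``(0, 1]`` — the same
ridit-type score used by the slope and relative indices of inequality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EDUCATION_LEVELS",
    "SurveySchema",
    "SurveyTable",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "resolve_household_education",
    "exclude_incomplete",
    "ses_rank",
]

#: Five-level parental education scale, lowest to highest.
DEFAULT_EDUCATION_LEVELS: tuple[str, ...] = (
    "primary_or_less",
    "some_secondary",
    "completed_secondary",
    "some_college",
    "completed_college",
)

_CORE_COLUMNS = (
    "respondent_id",
    "country",
    "cluster",
    "year",
    "gender",
    "outcome",
    "edu_mother",
    "edu_father",
)


class SurveyValidationError(ValueError):
    """Raised when input rows violate the survey contract.

    Carries the offending row numbers (0-based, excluding the header) in
    ``rows`` so callers can report them.
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class SurveySchema:
    """Column mapping and coding conventions for a survey CSV.

    Parameters
    ----------
    columns
        Mapping from logical field names (``respondent_id``, ``country``,
        ``cluster``, ``year``, ``gender``, ``outcome``, ``edu_mother``,
        ``edu_father``) to the column names in the file.  Identity by
        default.
    education_levels
        Ordered education categories, lowest first.
    missing_values
        Strings treated as missing for the education columns (in addition
        to the empty string).  "Don't know" / "does not apply" style codes
        belong here.
    genders
        Admissible gender codes.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in _CORE_COLUMNS}
    )
    education_levels: tuple[str, ...] = DEFAULT_EDUCATION_LEVELS
    missing_values: tuple[str, ...] = ("", "dont_know", "does_not_apply", "NA")
    genders: tuple[str, ...] = ("boy", "girl")

    def file_column(self, logical: str) -> str:
        return dict(self.columns).get(logical, logical)


@dataclass
class SurveyTable:
    """Validated respondent-level survey data.

    ``data`` always carries the core columns; ``ses`` (the fractional-rank
    score) and ``edu`` (resolved household education code, ``-1`` for
    missing) appear after the corresponding processing steps.
    ``exclusions`` records how many rows each cleaning step removed.
    """

    data: pd.DataFrame
    schema: SurveySchema = field(default_factory=SurveySchema)
    exclusions: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_ses(self) -> bool:
        return "ses" in self.data.columns

    def with_data(self, data: pd.DataFrame) -> "SurveyTable":
        return SurveyTable(data=data, schema=self.schema, exclusions=dict(self.exclusions))

    def attach_regions(self, region_map: Mapping[str, str]) -> "SurveyTable":
        """Add a ``region`` column from a country→region mapping.

        Countries absent from the map get region ``"other"``.
        """
        out = self.data.copy()
        out["region"] = out["country"].map(dict(region_map)).fillna("other")
        return self.with_data(out)

    def write_exclusion_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.exclusions, indent=2, sort_keys=True))


def _edu_codes(values: pd.Series, schema: SurveySchema) -> pd.Series:
    """Map education strings to ordinal codes; missing → -1."""
    values = values.astype("string")
    missing = values.isna() | values.isin(list(schema.missing_values))
    cat = pd.Categorical(values, categories=list(schema.education_levels), ordered=True)
    codes = pd.Series(cat.codes, index=values.index).astype(int)
    bad = (codes == -1) & ~missing
    if bad.any():
        rows = list(values.index[bad][:20])
        raise SurveyValidationError(
            f"unknown education categories at rows {rows}: "
            f"{sorted(values[bad].unique().tolist())}",
            rows,
        )
    return codes


def read_survey(path: str | Path, schema: SurveySchema | None = None) -> SurveyTable:
    """Read and validate a respondent-level CSV.

    Raises
    ------
    SurveyValidationError
        If a mandatory column is missing, the file has no data rows, or a
        row fails a type/domain check (offending row numbers included).
    """
    schema = schema or SurveySchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise SurveyValidationError(f"no data rows in {path}")
    rename = {schema.file_column(c): c for c in _CORE_COLUMNS}
    missing_cols = [f for f in rename if f not in df.columns]
    if missing_cols:
        raise SurveyValidationError(
            f"missing mandatory column(s) {missing_cols} in {path}"
        )
    df = df.rename(columns=rename)[list(_CORE_COLUMNS)]
    return _validate(df, schema)


def _validate(df: pd.DataFrame, schema: SurveySchema) -> SurveyTable:
    df = df.copy().reset_index(drop=True)

    year = pd.to_numeric(df["year"], errors="coerce")
    bad = year.isna() | (year != year.round())
    if bad.any():
        raise SurveyValidationError(
            f"non-integer year at rows {list(df.index[bad][:20])}", list(df.index[bad])
        )
    df["year"] = year.astype(int)

    out_raw = df["outcome"].astype("string")
    out_missing = out_raw.isna() | (out_raw == "") | out_raw.isin(list(schema.missing_values))
    out_num = pd.to_numeric(out_raw.where(~out_missing), errors="coerce")
    bad = (~out_missing) & (~out_num.isin([0, 1]))
    if bad.any():
        raise SurveyValidationError(
            f"outcome not in {{0,1}} at rows {list(df.index[bad][:20])}",
            list(df.index[bad]),
        )
    # keep missing as NaN until the exclusion step
    df["outcome"] = out_num.astype(float)

    bad = ~df["gender"].isin(list(schema.genders))
    if bad.any():
        raise SurveyValidationError(
            f"unknown gender codes at rows {list(df.index[bad][:20])}",
            list(df.index[bad]),
        )

    bad = (df["cluster"].astype("string").isna()) | (df["cluster"] == "")
    if bad.any():
        raise SurveyValidationError(
            f"missing cluster at rows {list(df.index[bad][:20])}", list(df.index[bad])
        )

    _edu_codes(df["edu_mother"], schema)
    _edu_codes(df["edu_father"], schema)
    return SurveyTable(data=df, schema=schema)


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write a table back to CSV in the schema's file column names."""
    df = table.data.copy()
    out = df["outcome"]
    df["outcome"] = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    rename = {c: table.schema.file_column(c) for c in _CORE_COLUMNS}
    cols = [c for c in df.columns if c in _CORE_COLUMNS] + [
        c for c in df.columns if c not in _CORE_COLUMNS
    ]
    df[cols].rename(columns=rename).to_csv(path, index=False)


def resolve_household_education(edu_mother, edu_father):
    """Household education = the more highly educated parent.

    Operates on ordinal codes (``-1`` or ``None``/NaN = missing).  If one
    parent's education is missing the other's is used; if both are missing
    the result is missing (``-1``).  Symmetric in its arguments.

    Accepts scalars or aligned array-likes.
    """

    def norm(v):
        a = np.asarray(v, dtype=float)
        a = np.where(np.isnan(a), -1.0, a)
        return a

    m, f = norm(edu_mother), norm(edu_father)
    res = np.maximum(m, f)
    if res.ndim == 0:
        return int(res)
    return res.astype(int)


def exclude_incomplete(table: SurveyTable) -> SurveyTable:
    """Drop rows unusable for analysis, recording counts by reason.

    A row is dropped when its outcome is missing and/or when both parents'
    education is missing.  The resolved household education code is stored
    in column ``edu``.
    """
    df = table.data.copy()
    m = _edu_codes(df["edu_mother"], table.schema)
    f = _edu_codes(df["edu_father"], table.schema)
    df["edu"] = resolve_household_education(m, f)

    miss_outcome = df["outcome"].isna()
    miss_ses = df["edu"] == -1
    excl = dict(table.exclusions)
    excl["missing_outcome"] = int(miss_outcome.sum())
    excl["missing_ses"] = int(miss_ses.sum())
    excl["excluded_total"] = int((miss_outcome | miss_ses).sum())

    kept = df.loc[~(miss_outcome | miss_ses)].copy()
    kept["outcome"] = kept["outcome"].astype(int)
    return SurveyTable(data=kept.reset_index(drop=True), schema=table.schema, exclusions=excl)


def ses_rank(table: SurveyTable, mode: str = "pooled") -> SurveyTable:
    """Attach the within-country fractional-rank SES score.

    Within each country, respondents are ranked by household education
    with ties resolved to the mean rank of the category group; the rank is
    divided by the number of scored respondents in that country, giving a
    score in ``(0, 1]``.  ``mode="pooled"`` (default) ranks each country's
    sample pooled over survey waves; ``mode="per-wave"`` ranks within each
    country×year cell instead.

    Requires resolved household education; rows with missing education
    must already be excluded (see :func:`exclude_incomplete`).
    """
    if mode not in ("pooled", "per-wave"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    df = table.data.copy()
    if "edu" not in df.columns:
        raise ValueError("household education not resolved; run exclude_incomplete first")
    if (df["edu"] < 0).any():
        raise ValueError("missing household education present; exclude first")
    keys = ["country"] if mode == "pooled" else ["country", "year"]
    grouped = df.groupby(keys, sort=False)["edu"]
    df["ses"] = grouped.rank(method="average") / grouped.transform("size")
    return table.with_data(df)
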