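"""Fish sampling records: the atomic input of the assessment.

One record is one sampled fish: the group (tributary) it came from, its sex,
its age in whole years from otolith annulus counts, body length in mm and body
weight in g.  Records travel through the pipeline as a pandas DataFrame with
the canonical column schema below; :class:`FishRecord` is the row-level view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import ValidationError

SEXES = ("female", "male", "unknown")

#: canonical CSV / DataFrame schema, in order
COLUMNS = ("group_id", "sex", "age", "length_mm", "weight_g")


@dataclass(frozen=True)
class FishRecord:
    """A single sampled fish."""

    group_id: str
    sex: str  # one of SEXES
    age: int  # whole years (annulus count at capture)
    length_mm: float  # body length, mm, > 0
    weight_g: float  # body weight, g, > 0


def as_frame(records) -> pd.DataFrame:
    """Coerce an iterable of FishRecord, list of dicts, or DataFrame to the
    canonical schema (a no-op pass-through for a conforming DataFrame)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and isinstance(records[0], FishRecord):
            df = pd.DataFrame([r.__dict__ for r in records])
        else:
            df = pd.DataFrame(records)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"records are missing columns: {missing}")
    return df[list(COLUMNS)]


def validate_records(df: pd.DataFrame, groups: Iterable[str] | None = None) -> pd.DataFrame:
    """Validate the record schema and value invariants.

    Raises :class:`ValidationError` naming the first offending row.  ``groups``
    optionally restricts ``group_id`` to a configured set.
    """
    df = as_frame(df)

    def first_bad(mask, what, col):
        if mask.any():
            idx = df.index[mask][0]
            raise ValidationError(f"row {idx}: {what}, got {df.loc[idx, col]!r}")

    first_bad(~(df["length_mm"] > 0), "body length must be > 0", "length_mm")
    first_bad(~(df["weight_g"] > 0), "body weight must be > 0", "weight_g")
    age = pd.to_numeric(df["age"], errors="coerce")
    first_bad(age.isna() | (age < 0) | (age != age.round()),
              "age must be a non-negative integer", "age")
    first_bad(~df["sex"].isin(SEXES), f"sex must be one of {SEXES}", "sex")
    if groups is not None:
        first_bad(~df["group_id"].isin(set(groups)), "unknown group_id", "group_id")
    return df


def read_records(path, groups: Iterable[str] | None = None) -> pd.DataFrame:
    """Read records from a UTF-8 CSV with the canonical header and validate."""
    df = pd.read_csv(path, encoding="utf-8")
    return validate_records(df, groups=groups)


def write_records(df: pd.DataFrame, path) -> None:
    """Write records to CSV in the canonical column order (round-trips with
    :func:`read_records`)."""
    as_frame(df).to_csv(path, index=False, encoding="utf-8")
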