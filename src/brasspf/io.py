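"""CSV reading/writing for schedules, microdata and result reports.

Schedules travel as plain UTF-8 CSV, one row per age group, because no
standard interchange format exists for ASFR/parity data.  Column
conventions:

========== =============================================================
schema     required columns (optional in brackets)
========== =============================================================
fertility  ``age_lower, asfr_interval`` (or ``asfr`` + explicit scale)
           [``asfr_se``]
parity     ``age_lower, ceb_mean`` [``ceb_se, ceb_n``]
combined   fertility + parity columns in one table
microdata  ``age_group, birth_last_12m, ceb`` (one row per woman)
mortality  ``age_lower, L``
========== =============================================================

Lines starting with ``#`` hold report metadata and are skipped on read.
The ASFR scale is never guessed: it comes from the column name
(``asfr_interval``) or an explicit ``scale`` argument.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .ages import AgeGroupGrid
from .growth import MortalitySchedule
from .schedules import INTERVAL, FertilitySchedule, ParitySchedule

logger = logging.getLogger(__name__)

SCHEMAS = ("fertility", "parity", "combined", "microdata", "mortality")

_REQUIRED = {
    "fertility": [["age_lower"], ["asfr_interval", "asfr"]],
    "parity": [["age_lower"], ["ceb_mean"]],
    "combined": [["age_lower"], ["asfr_interval", "asfr"], ["ceb_mean"]],
    "microdata": [["age_group"], ["birth_last_12m"], ["ceb"]],
    "mortality": [["age_lower"], ["L"]],
}


def _load(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, no header to match a schema") from None
    if df.empty:
        raise ValueError(f"{path}: header only, no data rows")
    return df


def _check_columns(df: pd.DataFrame, schema: str, path) -> None:
    for alternatives in _REQUIRED[schema]:
        if not any(c in df.columns for c in alternatives):
            raise ValueError(
                f"{path}: schema '{schema}' requires a column "
                f"{' or '.join(repr(c) for c in alternatives)}"
            )


def _numeric(df: pd.DataFrame, col: str, path, nonnegative: bool = True) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.index[values.isna() & df[col].notna()]
    if len(bad):
        # +2: 1-based counting plus the header line
        raise ValueError(f"{path}: malformed value in column {col!r}, row {bad[0] + 2}")
    missing = values.index[values.isna()]
    if len(missing):
        raise ValueError(f"{path}: missing value in column {col!r}, row {missing[0] + 2}")
    arr = values.to_numpy(float)
    if nonnegative and np.any(arr < 0):
        row = int(np.flatnonzero(arr < 0)[0]) + 2
        raise ValueError(f"{path}: negative value in column {col!r}, row {row}")
    return arr


def _grid_from(df: pd.DataFrame, path) -> AgeGroupGrid:
    lowers = _numeric(df, "age_lower", path).astype(int)
    if len(lowers) > 1:
        width = int(lowers[1] - lowers[0])
    else:
        width = 5
    try:
        return AgeGroupGrid(tuple(int(x) for x in lowers), width if width > 0 else 5)
    except ValueError as exc:
        raise ValueError(f"{path}: bad age_lower column: {exc}") from None


def read_schedule_csv(path, schema: str, scale: str = INTERVAL):
    """Read and validate a CSV into the matching domain object(s).

    Returns a :class:`FertilitySchedule`, :class:`ParitySchedule`, a
    ``(fertility, parity)`` pair, a microdata ``DataFrame`` or a
    :class:`MortalitySchedule` depending on ``schema``.  Malformed rows,
    missing columns and non-contiguous age grids are rejected with the
    offending row named.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {SCHEMAS}")
    df = _load(path)
    _check_columns(df, schema, path)

    if schema == "microdata":
        for col in ("age_group", "birth_last_12m", "ceb"):
            _numeric(df, col, path)
        if not df["birth_last_12m"].isin((0, 1)).all():
            raise ValueError(f"{path}: birth_last_12m must be a 0/1 indicator")
        return df[["age_group", "birth_last_12m", "ceb"]].astype(int)

    grid = _grid_from(df, path)

    if schema == "mortality":
        return MortalitySchedule(grid, _numeric(df, "L", path))

    fert = par = None
    if schema in ("fertility", "combined"):
        if "asfr_interval" in df.columns:
            f, f_scale = _numeric(df, "asfr_interval", path), INTERVAL
        else:
            f, f_scale = _numeric(df, "asfr", path), scale
        se = _numeric(df, "asfr_se", path) if "asfr_se" in df.columns else None
        if se is None and {"births_p", "births_n"} <= set(df.columns):
            from .stochastic import binomial_rate_distribution

            p = _numeric(df, "births_p", path)
            n = _numeric(df, "births_n", path).astype(int)
            se = np.array(
                [binomial_rate_distribution(pi, ni, scale=INTERVAL).sd for pi, ni in zip(p, n)]
            )
        fert = FertilitySchedule(grid, f, scale=f_scale, se=se).to_interval()
    if schema in ("parity", "combined"):
        par = ParitySchedule(
            grid,
            _numeric(df, "ceb_mean", path),
            se=_numeric(df, "ceb_se", path) if "ceb_se" in df.columns else None,
            n=_numeric(df, "ceb_n", path).astype(int) if "ceb_n" in df.columns else None,
        )
    if schema == "fertility":
        return fert
    if schema == "parity":
        return par
    return fert, par


def write_schedule_csv(path, fertility: FertilitySchedule, parity: Optional[ParitySchedule] = None):
    """Write schedules at full precision (lossless round trip with the reader)."""
    fert = fertility.to_interval()
    data = {"age_lower": fert.grid.lower_bounds, "asfr_interval": fert.f}
    if fert.se is not None:
        data["asfr_se"] = fert.se
    if parity is not None:
        data["ceb_mean"] = parity.P
        if parity.se is not None:
            data["ceb_se"] = parity.se
        if parity.n is not None:
            data["ceb_n"] = parity.n
    pd.DataFrame(data).to_csv(path, index=False)


def write_report(results, path, emulate_paper_rounding: bool = False) -> None:
    """Write a results table mirroring the worked-example layout.

    Deterministic results produce columns ``age_group, asfr,
    cum_fertility, ceb, pf_ratio, adjusted_asfr``; stochastic results
    replace the ratio column with ``lower95, upper95`` and prepend a
    ``#``-commented metadata block (ratio mean/sd, draws, seed, interval
    mode, rejections).  A final TFR row sums the schedule columns.  With
    ``emulate_paper_rounding`` every value is rounded half-up to 3
    decimals, as the published tables print them.
    """
    df = results.to_frame(emulate_paper_rounding=emulate_paper_rounding)
    tfr_row = {c: "" for c in df.columns}
    tfr_row["age_group"] = "TFR"
    for col in ("asfr", "adjusted_asfr", "lower95", "upper95"):
        if col in df.columns:
            total = {
                "asfr": results.model.fertility.tfr,
                "adjusted_asfr": results.adjusted.tfr_adj,
                "lower95": results.adjusted.tfr_lower,
                "upper95": results.adjusted.tfr_upper,
            }[col]
            if total is not None:
                tfr_row[col] = round_half_up(total, 3) if emulate_paper_rounding else total
    out = pd.concat([df, pd.DataFrame([tfr_row])], ignore_index=True)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        metadata = getattr(results, "metadata", None)
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key} = {value}\n")
        out.to_csv(fh, index=False)
    logger.info("report written to %s", path)


def read_report(path):
    """Read a report back: ``(table, metadata_dict)``; TFR row excluded."""
    path = Path(path)
    metadata = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition("=")
            metadata[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    df = df[df["age_group"] != "TFR"].reset_index(drop=True)
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col])
    return df, metadata
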