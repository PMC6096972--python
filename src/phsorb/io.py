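"""CSV dialects, bundled tables and report serialization.

Dialects (comma delimiter, period decimal, UTF-8, empty cell = absent):

* compound table — ``name,cas,mw_g_per_mol,log_kow,pka,ion_class,ws_sub_mol_per_L``
* measurements   — ``compound,polymer,ph,replicate,time_days,c0_ug_per_L,cw_ug_per_L``
* fit report     — per compound: rendered coefficient tokens (numeric,
  ``<5e+01`` censored, ``n.a.``) plus numeric shadow columns.

Three tables ship with the package: the 19-compound property table and
the published fitted-coefficient tables for polyethylene and polystyrene
(used as regression references for the reporting layer and as default
ground truths for the synthetic generator).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .compounds import CompoundRecord
from .errors import InvalidInputError, ParseError

COMPOUND_HEADER = [
    "name",
    "cas",
    "mw_g_per_mol",
    "log_kow",
    "pka",
    "ion_class",
    "ws_sub_mol_per_L",
]

MEASUREMENT_HEADER = [
    "compound",
    "polymer",
    "ph",
    "replicate",
    "time_days",
    "c0_ug_per_L",
    "cw_ug_per_L",
]

_FIT_TABLES = {"PE": "fits_table2_pe.csv", "PS": "fits_table3_ps.csv"}


def bundled_path(name: str) -> Path:
    """Path to a bundled data table by file name."""
    return Path(str(resources.files("phsorb").joinpath("data", name)))


def format_sci(x: float, sig: int = 12) -> str:
    """Scientific-notation string with ``sig`` significant digits."""
    return f"{x:.{sig - 1}e}"


def _parse_float(cell: str, row: int, column: str, *, required: bool) -> float | None:
    cell = cell.strip()
    if cell == "":
        if required:
            raise ParseError(f"row {row}, column {column!r}: value required")
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"row {row}, column {column!r}: not a number: {cell!r}"
        ) from None


def read_compound_table(path: str | Path | None = None) -> list[CompoundRecord]:
    """Read a compound property table; defaults to the bundled table.

    Raises :class:`ParseError` naming row and column for malformed
    headers or cells; record-level invariants are enforced by
    :class:`~phsorb.compounds.CompoundRecord`.
    """
    if path is None:
        path = bundled_path("compounds_table1.csv")
    records: list[CompoundRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header") from None
        if [h.strip() for h in header] != COMPOUND_HEADER:
            raise ParseError(
                f"{path}: bad header {header!r}, expected {COMPOUND_HEADER!r}"
            )
        for i, row in enumerate(reader, start=2):
            if len(row) != len(COMPOUND_HEADER):
                raise ParseError(
                    f"row {i}: expected {len(COMPOUND_HEADER)} cells, got {len(row)}"
                )
            name, cas = row[0].strip(), row[1].strip()
            mw = _parse_float(row[2], i, "mw_g_per_mol", required=True)
            log_kow = _parse_float(row[3], i, "log_kow", required=True)
            pka = _parse_float(row[4], i, "pka", required=False)
            ion_class = row[5].strip().lower()
            ws_sub = _parse_float(row[6], i, "ws_sub_mol_per_L", required=False)
            try:
                records.append(
                    CompoundRecord(
                        name=name,
                        cas=cas,
                        mw=mw,
                        log_kow=log_kow,
                        pka=pka,
                        ion_class=ion_class,
                        ws_sub=ws_sub,
                    )
                )
            except InvalidInputError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
    return records


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write compound records in the compound-table dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COMPOUND_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.name,
                    r.cas,
                    repr(r.mw),
                    repr(r.log_kow),
                    "" if r.pka is None else repr(r.pka),
                    r.ion_class,
                    "" if r.ws_sub is None else repr(r.ws_sub),
                ]
            )


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement table, validating header and cell types."""
    df = pd.read_csv(path)
    if list(df.columns) != MEASUREMENT_HEADER:
        raise ParseError(
            f"{path}: bad header {list(df.columns)!r}, "
            f"expected {MEASUREMENT_HEADER!r}"
        )
    for col in ("ph", "time_days", "c0_ug_per_L", "cw_ug_per_L"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ParseError(f"column {col!r}: {exc}") from exc
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise ParseError(f"column 'replicate': {exc}") from exc
    if (df["cw_ug_per_L"] < 0).any():
        bad = int(df.index[df["cw_ug_per_L"] < 0][0]) + 2
        raise ParseError(f"row {bad}, column 'cw_ug_per_L': negative concentration")
    return df


def read_fit_table(
    polymer_or_path: str | Path,
) -> pd.DataFrame:
    """Read a published-style fit table ("PE", "PS", or a path).

    Parses the report tokens into numeric shadows and flags:
    ``kp_n_value``/``kp_i_value`` (NaN when censored or n.a.),
    ``kp_n_censored``, ``kp_i_censored``, ``kp_i_na``, plus the per-pH
    CV columns ``cv_ph4``, ``cv_ph7``, ``cv_ph10``.
    """
    if str(polymer_or_path).upper() in _FIT_TABLES:
        path = bundled_path(_FIT_TABLES[str(polymer_or_path).upper()])
    else:
        path = Path(polymer_or_path)
    df = pd.read_csv(path)

    def parse(token: str) -> tuple[float, bool, bool]:
        token = token.strip()
        if token == "n.a.":
            return float("nan"), False, True
        if token.startswith("<"):
            return float("nan"), True, False
        return float(token), False, False

    parsed_n = df["kp_n_report"].map(parse)
    parsed_i = df["kp_i_report"].map(parse)
    df["kp_n_value"] = [p[0] for p in parsed_n]
    df["kp_n_censored"] = [p[1] for p in parsed_n]
    df["kp_i_value"] = [p[0] for p in parsed_i]
    df["kp_i_censored"] = [p[1] for p in parsed_i]
    df["kp_i_na"] = [p[2] for p in parsed_i]
    return df
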