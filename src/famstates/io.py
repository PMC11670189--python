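"""CSV input/output with schema validation and column-mapping adapters.

Native input schema (three delimited tables):

``children.csv``
    child_id, sex (female|male|unknown; blank = unknown), birth_year,
    twin (0/1), birth_order, mother_id, father_id (blank or "EXTERNAL"
    = external), death_year (blank = alive/censored), last_observed_year.
``marriages.csv``
    parent_id, spouse_id, start_year, end_year (blank = open union).
``vitals.csv``
    parent_id, death_year (blank = none), known (0/1; default 1).

Deposited datasets with different headers are adapted through a column
mapping (YAML or dict): ``{"children": {"child_id": "their_name", ...},
"marriages": {...}, "vitals": {...}, "values": {"external": "<code>"}}``.
Unmapped columns keep their native names, so a mapping only lists the
columns that differ.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .records import (
    EXTERNAL,
    ChildRecord,
    MarriageSpell,
    ParentVital,
    Sex,
    ValidationError,
)

CHILD_COLUMNS = (
    "child_id", "sex", "birth_year", "twin", "birth_order",
    "mother_id", "father_id", "death_year", "last_observed_year",
)
MARRIAGE_COLUMNS = ("parent_id", "spouse_id", "start_year", "end_year")
VITAL_COLUMNS = ("parent_id", "death_year", "known")


def load_column_mapping(path) -> dict:
    """Read a YAML column-mapping config."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ValidationError("column mapping must be a mapping of tables")
    return mapping


def _apply_mapping(df: pd.DataFrame, table: str, mapping: Optional[dict]) -> pd.DataFrame:
    if not mapping:
        return df
    table_map = mapping.get(table, {})
    rename = {v: k for k, v in table_map.items()}
    return df.rename(columns=rename)


def _require(df: pd.DataFrame, cols: Sequence[str], table: str, optional=()) -> None:
    missing = [c for c in cols if c not in df.columns and c not in optional]
    if missing:
        raise ValidationError(
            f"{table}: missing required columns {missing}; present: "
            f"{list(df.columns)} (use a column mapping to adapt)"
        )


def _norm_id(value, external_code: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return EXTERNAL
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "na") or s == external_code:
        return EXTERNAL
    return s


def _opt_year(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "na"):
        return None
    return int(float(s))


_SEX = {
    "female": Sex.FEMALE, "f": Sex.FEMALE, "0": Sex.FEMALE,
    "male": Sex.MALE, "m": Sex.MALE, "1": Sex.MALE,
    "unknown": Sex.UNKNOWN, "": Sex.UNKNOWN, "nan": Sex.UNKNOWN,
    "na": Sex.UNKNOWN,
}


def read_children(path, mapping: Optional[dict] = None) -> List[ChildRecord]:
    df = _apply_mapping(pd.read_csv(path, dtype=str), "children", mapping)
    _require(df, CHILD_COLUMNS, "children", optional=("death_year",))
    external_code = (mapping or {}).get("values", {}).get("external", EXTERNAL)
    out = []
    for i, row in df.iterrows():
        try:
            sex_raw = str(row.get("sex", "")).strip().lower()
            if sex_raw not in _SEX:
                raise ValidationError(f"unrecognized sex value {row['sex']!r}")
            out.append(
                ChildRecord(
                    child_id=str(row["child_id"]).strip(),
                    sex=_SEX[sex_raw],
                    birth_year=int(float(row["birth_year"])),
                    twin=bool(int(float(row["twin"]))),
                    birth_order=int(float(row["birth_order"])),
                    mother_id=_norm_id(row["mother_id"], external_code),
                    father_id=_norm_id(row["father_id"], external_code),
                    death_year=_opt_year(row.get("death_year")),
                    last_observed_year=int(float(row["last_observed_year"])),
                )
            )
        except (ValueError, ValidationError) as err:
            raise ValidationError(f"children row {i}: {err}") from err
    return out


def read_marriages(path, mapping: Optional[dict] = None) -> List[MarriageSpell]:
    df = _apply_mapping(pd.read_csv(path, dtype=str), "marriages", mapping)
    _require(df, MARRIAGE_COLUMNS, "marriages", optional=("end_year",))
    external_code = (mapping or {}).get("values", {}).get("external", EXTERNAL)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                MarriageSpell(
                    parent_id=_norm_id(row["parent_id"], external_code),
                    spouse_id=_norm_id(row["spouse_id"], external_code),
                    start_year=int(float(row["start_year"])),
                    end_year=_opt_year(row.get("end_year")),
                )
            )
        except (ValueError, ValidationError) as err:
            raise ValidationError(f"marriages row {i}: {err}") from err
    return out


def read_vitals(path, mapping: Optional[dict] = None) -> List[ParentVital]:
    df = _apply_mapping(pd.read_csv(path, dtype=str), "vitals", mapping)
    _require(df, VITAL_COLUMNS, "vitals", optional=("known", "death_year"))
    out = []
    for i, row in df.iterrows():
        try:
            known_raw = row.get("known")
            known = True
            if known_raw is not None and str(known_raw).strip() not in ("", "nan"):
                known = bool(int(float(known_raw)))
            out.append(
                ParentVital(
                    parent_id=str(row["parent_id"]).strip(),
                    death_year=_opt_year(row.get("death_year")),
                    known=known,
                )
            )
        except (ValueError, ValidationError) as err:
            raise ValidationError(f"vitals row {i}: {err}") from err
    return out


def load_tables(
    children_path,
    marriages_path,
    vitals_path,
    mapping: Optional[dict] = None,
) -> Tuple[List[ChildRecord], List[MarriageSpell], List[ParentVital]]:
    """Read and validate the three input tables."""
    return (
        read_children(children_path, mapping),
        read_marriages(marriages_path, mapping),
        read_vitals(vitals_path, mapping),
    )


def write_tables(
    outdir,
    records: Sequence[ChildRecord],
    spells: Sequence[MarriageSpell],
    vitals: Sequence[ParentVital],
) -> Dict[str, Path]:
    """Write the three tables in the native schema; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    children = pd.DataFrame(
        [
            {
                "child_id": c.child_id,
                "sex": c.sex.value,
                "birth_year": c.birth_year,
                "twin": int(c.twin),
                "birth_order": c.birth_order,
                "mother_id": c.mother_id,
                "father_id": c.father_id,
                "death_year": c.death_year,
                "last_observed_year": c.last_observed_year,
            }
            for c in records
        ]
    )
    paths["children"] = outdir / "children.csv"
    children.to_csv(paths["children"], index=False)
    sp = pd.DataFrame(
        [
            {
                "parent_id": s.parent_id,
                "spouse_id": s.spouse_id,
                "start_year": s.start_year,
                "end_year": s.end_year,
            }
            for s in spells
        ]
    )
    paths["marriages"] = outdir / "marriages.csv"
    sp.to_csv(paths["marriages"], index=False)
    vt = pd.DataFrame(
        [
            {
                "parent_id": v.parent_id,
                "death_year": v.death_year,
                "known": int(v.known),
            }
            for v in vitals
        ]
    )
    paths["vitals"] = outdir / "vitals.csv"
    vt.to_csv(paths["vitals"], index=False)
    return paths


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    panel["child_id"] = panel["child_id"].astype(str)
    panel["mother_id"] = panel["mother_id"].astype(str)
    panel["father_id"] = panel["father_id"].astype(str)
    return panel


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
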