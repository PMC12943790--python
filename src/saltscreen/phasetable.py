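"""Reading and writing phase tables (CSV and JSON).

The external table schema has one row per crystalline phase with columns
``name, role, formula, molar_mass, t_fus, t_fus_unit (C|K), dh_fus,
dh_fus_unit (J/mol|J/g), coord1, coord2, coord3``.  A missing molar mass is
computed from the formula; a missing formula requires the molar mass only
when a specific (J/g) enthalpy must be converted.  JSON files use the same
keys, either as a bare list of records or as an object with a ``phases``
list (optionally ``base_components`` and ``explicit_triplets``, as in the
packaged case files).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .datasets import CaseStudy
from .phases import CrystallinePhase

__all__ = ["read_phase_table", "write_phase_table_csv", "write_phase_table_json"]

_CSV_COLUMNS = [
    "name", "role", "formula", "molar_mass",
    "t_fus", "t_fus_unit", "dh_fus", "dh_fus_unit",
    "coord1", "coord2", "coord3",
]


def _clean(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def read_phase_table(path: Union[str, Path]) -> CaseStudy:
    """Load a phase table from a ``.csv`` or ``.json`` file."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        records = [
            {k: _clean(v) for k, v in row.items()} for row in df.to_dict("records")
        ]
        phases = [CrystallinePhase.from_record(r) for r in records]
        return CaseStudy(
            label=path.stem,
            description=f"phase table read from {path.name}",
            base_components=("component-1", "component-2", "component-3"),
            phases=phases,
        )
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        if isinstance(raw, list):
            raw = {"phases": raw}
        phases = [
            CrystallinePhase.from_record({k: _clean(v) for k, v in r.items()})
            for r in raw["phases"]
        ]
        return CaseStudy(
            label=raw.get("label", path.stem),
            description=raw.get("description", f"phase table read from {path.name}"),
            base_components=tuple(
                raw.get("base_components", ("component-1", "component-2", "component-3"))
            ),
            phases=phases,
            explicit_triplets=[list(t) for t in raw.get("explicit_triplets", [])],
            extras=raw.get("extras", {}),
        )
    raise ValueError(f"unsupported phase-table format {path.suffix!r} (use .csv or .json)")


def _records(phases: Sequence[CrystallinePhase]) -> list[dict]:
    out = []
    for p in phases:
        rec = p.to_record()
        rec["coord1"], rec["coord2"], rec["coord3"] = rec.pop("coords")
        out.append(rec)
    return out


def write_phase_table_csv(phases: Sequence[CrystallinePhase], path: Union[str, Path]) -> None:
    df = pd.DataFrame(_records(phases))[_CSV_COLUMNS]
    df.to_csv(path, index=False)


def write_phase_table_json(
    case: CaseStudy, path: Union[str, Path], indent: Optional[int] = 2
) -> None:
    payload = {
        "label": case.label,
        "description": case.description,
        "base_components": list(case.base_components),
        "explicit_triplets": case.explicit_triplets,
        "phases": [p.to_record() for p in case.phases],
        "extras": case.extras,
    }
    Path(path).write_text(json.dumps(payload, indent=indent))
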