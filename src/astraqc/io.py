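"""CSV ingest and export.

Two registered table schemas are supported:

* ``contents`` — one row per sample with metadata and the seven
  sweetness-component contents, columns named with their assay unit
  (``glc_ug_g`` ... ``suc_mg_g``, ``betaine_mg_g``). Values are
  converted to the canonical mg/g scale on read.
* ``indicators`` — one row per sample with the four pharmacopoeia
  indicator values (``calycosin_glucoside_mg_g`` ...,
  ``polysaccharides_g_g``, ``extracts_g_g``).

Unknown columns in a contents table are carried through on the record's
``extra`` mapping and excluded from every computation, so tables with
additional assay columns pass through unharmed.

All files are comma-separated UTF-8 with a header row and "." decimals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .records import (
    IndicatorPanel,
    SampleRecord,
    SchemaError,
    SweetnessReference,
    ValidationError,
)
from .units import Unit, convert_unit, to_canonical

#: contents-schema column -> (component name, unit the column is stated in)
CONTENT_COLUMNS: dict[str, tuple[str, Unit]] = {
    "glc_ug_g": ("glucose", Unit.UG_PER_G),
    "fru_ug_g": ("fructose", Unit.UG_PER_G),
    "ino_ug_g": ("inositol", Unit.UG_PER_G),
    "sor_ug_g": ("sorbitol", Unit.UG_PER_G),
    "dul_ug_g": ("dulcitol", Unit.UG_PER_G),
    "suc_mg_g": ("sucrose", Unit.MG_PER_G),
    "betaine_mg_g": ("betaine", Unit.MG_PER_G),
}

METADATA_COLUMNS = ("sample_id", "species", "region", "growth_years", "cultivation")

#: indicators-schema column -> indicator name
INDICATOR_COLUMNS: dict[str, str] = {
    "calycosin_glucoside_mg_g": "calycosin_glucoside",
    "astragaloside_iv_mg_g": "astragaloside_iv",
    "polysaccharides_g_g": "polysaccharides",
    "extracts_g_g": "extracts",
}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read a contents-schema CSV into validated sample records.

    Row order is preserved. Negative or non-numeric contents raise a
    :class:`ValidationError` naming the offending sample.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, list(METADATA_COLUMNS) + list(CONTENT_COLUMNS), path)
    known = set(METADATA_COLUMNS) | set(CONTENT_COLUMNS)
    extra_cols = [c for c in df.columns if c not in known]

    records = []
    for _, row in df.iterrows():
        contents = {}
        for col, (component, unit) in CONTENT_COLUMNS.items():
            raw = float(row[col])
            if raw < 0:
                raise ValidationError(
                    f"sample {row['sample_id']!r}: negative content in "
                    f"column {col!r} ({raw})"
                )
            contents[component] = to_canonical(raw, unit)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                species=str(row["species"]),
                region=str(row["region"]),
                growth_years=int(row["growth_years"]),
                cultivation=str(row["cultivation"]),
                contents=contents,
                extra={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_samples(samples: Sequence[SampleRecord], path: str | Path) -> None:
    """Write sample records as a contents-schema CSV (inverse of read)."""
    rows = []
    for s in samples:
        row: dict = {
            "sample_id": s.sample_id,
            "species": s.species,
            "region": s.region,
            "growth_years": s.growth_years,
            "cultivation": s.cultivation,
        }
        for col, (component, unit) in CONTENT_COLUMNS.items():
            row[col] = convert_unit(s.contents.get(component, 0.0), Unit.MG_PER_G, unit)
        row.update(s.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_indicators(path: str | Path) -> list[IndicatorPanel]:
    """Read an indicators-schema CSV into validated indicator panels."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id"] + list(INDICATOR_COLUMNS), path)
    panels = []
    for _, row in df.iterrows():
        panels.append(
            IndicatorPanel(
                sample_id=str(row["sample_id"]),
                **{name: float(row[col]) for col, name in INDICATOR_COLUMNS.items()},
            )
        )
    return panels


def write_indicators(panels: Sequence[IndicatorPanel], path: str | Path) -> None:
    """Write indicator panels as an indicators-schema CSV."""
    rows = [
        {
            "sample_id": p.sample_id,
            **{col: getattr(p, name) for col, name in INDICATOR_COLUMNS.items()},
        }
        for p in panels
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sweetness_reference(path: str | Path) -> SweetnessReference:
    """Read a relative-sweetness table (columns: component, relative_sweetness)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["component", "relative_sweetness"], path)
    weights = {
        str(row["component"]): float(row["relative_sweetness"])
        for _, row in df.iterrows()
    }
    return SweetnessReference(weights=weights)


def write_sweetness_reference(ref: SweetnessReference, path: str | Path) -> None:
    pd.DataFrame(
        {"component": list(ref.weights), "relative_sweetness": list(ref.weights.values())}
    ).to_csv(path, index=False)


# read_samples is exposed under a schema switch as well, mirroring the
# two-table interface of the pipeline.
def read_table(path: str | Path, schema: str):
    """Dispatch on registered schema name: ``contents`` or ``indicators``."""
    if schema == "contents":
        return read_samples(path)
    if schema == "indicators":
        return read_indicators(path)
    raise SchemaError(f"unknown schema {schema!r}; expected 'contents' or 'indicators'")
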