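"""Canonical TSV dialects and result writing.

Upstream search/quantification tools (database search, peptide-level
quantification) export tab-separated tables whose layouts vary by tool and
version. This module defines one canonical post-search schema per table kind
and validates rows into the domain record types. Third-party exports are
ingested by supplying a column-mapping config (source column -> canonical
column) as JSON or YAML.

Peptide table columns:  peptide, protein, heavy_area, light_area,
                        chase_time, genotype, replicate
Spectral-count columns: protein, bait, genotype, replicate, spec_count

All writers emit UTF-8, LF-terminated TSV. ``write_results`` sorts rows
canonically (by every column, left to right) and returns a manifest with row
counts and SHA-256 digests; the manifest carries no timestamps so identical
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    DuplicateKeyError,
    ParseError,
    SchemaError,
    ValidationError,
)
from .records import Bait, Genotype, PeptideQuantRecord, SpectralCountRecord

PEPTIDE_COLUMNS = ("peptide", "protein", "heavy_area", "light_area",
                   "chase_time", "genotype", "replicate")
SPECCOUNT_COLUMNS = ("protein", "bait", "genotype", "replicate", "spec_count")


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a source-column -> canonical-column mapping from JSON or YAML."""
    text = Path(path).read_text(encoding="utf-8")
    mapping = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(mapping, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in mapping.items()
    ):
        raise SchemaError(f"column map in {path} must be a flat string->string mapping")
    return mapping


def _read_raw(path: str | Path, columns: Sequence[str],
              column_map: Mapping[str, str] | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file does not exist: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path} is missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df[list(columns)]


def _parse_float(value: str, row: int, column: str) -> float:
    try:
        out = float(value)
    except ValueError:
        raise ParseError(f"cannot parse {value!r} as a number", row=row, column=column) from None
    if math.isnan(out):
        raise ParseError(f"missing/NaN value {value!r}", row=row, column=column)
    return out


def _parse_int(value: str, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"cannot parse {value!r} as an integer", row=row, column=column) from None


def read_peptide_table(path: str | Path,
                       column_map: Mapping[str, str] | None = None
                       ) -> list[PeptideQuantRecord]:
    """Read and validate a canonical peptide quantification TSV.

    Row order is preserved. Raises :class:`ParseError` /
    :class:`ValidationError` naming the offending 1-based file row, and
    :class:`DuplicateKeyError` when (peptide, protein, chase_time, genotype,
    replicate) repeats.
    """
    df = _read_raw(path, PEPTIDE_COLUMNS, column_map)
    records: list[PeptideQuantRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            rec = PeptideQuantRecord(
                peptide=row.peptide,
                protein=row.protein,
                heavy_area=_parse_float(row.heavy_area, i, "heavy_area"),
                light_area=_parse_float(row.light_area, i, "light_area"),
                chase_time=_parse_float(row.chase_time, i, "chase_time"),
                genotype=row.genotype,
                replicate=_parse_int(row.replicate, i, "replicate"),
            )
        except ValidationError as exc:
            raise ValidationError(str(exc), row=i) from None
        key = (rec.peptide, rec.protein, rec.chase_time, rec.genotype, rec.replicate)
        if key in seen:
            raise DuplicateKeyError(
                f"duplicate peptide observation {key} at row {i}; upstream "
                "quantifiers already aggregate per peptide, duplicates are rejected"
            )
        seen.add(key)
        records.append(rec)
    return records


def read_speccount_table(path: str | Path,
                         column_map: Mapping[str, str] | None = None
                         ) -> list[SpectralCountRecord]:
    """Read and validate a canonical IP spectral-count TSV."""
    df = _read_raw(path, SPECCOUNT_COLUMNS, column_map)
    records: list[SpectralCountRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = SpectralCountRecord(
                protein=row.protein,
                bait=row.bait,
                genotype=row.genotype,
                replicate=_parse_int(row.replicate, i, "replicate"),
                spec_count=_parse_int(row.spec_count, i, "spec_count"),
            )
        except ValidationError as exc:
            raise ValidationError(str(exc), row=i) from None
        key = (rec.bait, rec.genotype, rec.replicate, rec.protein)
        if key in seen:
            raise DuplicateKeyError(f"duplicate spectral-count row {key} at row {i}")
        seen.add(key)
        records.append(rec)
    return records


def peptide_records_to_frame(records: Iterable[PeptideQuantRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "peptide": [r.peptide for r in records],
            "protein": [r.protein for r in records],
            "heavy_area": [r.heavy_area for r in records],
            "light_area": [r.light_area for r in records],
            "chase_time": [r.chase_time for r in records],
            "genotype": [r.genotype.value for r in records],
            "replicate": [r.replicate for r in records],
        },
        columns=list(PEPTIDE_COLUMNS),
    )


def speccount_records_to_frame(records: Iterable[SpectralCountRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "bait": [r.bait.value for r in records],
            "genotype": [r.genotype.value for r in records],
            "replicate": [r.replicate for r in records],
            "spec_count": [r.spec_count for r in records],
        },
        columns=list(SPECCOUNT_COLUMNS),
    )


def _write_frame(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def write_peptide_table(records: Iterable[PeptideQuantRecord], path: str | Path) -> None:
    """Write records in their given order (round-trips with the reader)."""
    _write_frame(peptide_records_to_frame(records), path)


def write_speccount_table(records: Iterable[SpectralCountRecord], path: str | Path) -> None:
    _write_frame(speccount_records_to_frame(records), path)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  manifest_name: str = "manifest.json",
                  extra: Mapping | None = None) -> dict:
    """Write named result tables as canonical TSVs plus a manifest.

    Each table is sorted by all of its columns (left to right, stable) so the
    on-disk bytes are a pure function of content. The manifest lists file
    names, row counts and SHA-256 digests and is itself deterministic.
    """
    if tables is None:
        raise ValidationError("tables must not be None")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(tables):
        df = tables[name]
        if list(df.columns) and len(df) > 0:
            df = df.sort_values(by=list(df.columns), kind="mergesort").reset_index(drop=True)
        fname = f"{name}.tsv"
        fpath = out_dir / fname
        _write_frame(df, fpath)
        entries.append({"name": fname, "rows": int(len(df)), "sha256": sha256_of(fpath)})
    manifest = {"files": entries}
    if extra:
        manifest.update(extra)
    mpath = out_dir / manifest_name
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
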