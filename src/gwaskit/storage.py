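"""Persist harmonized tables and query many datasets as one logical dataset.

The default on-disk layout is hive-style chromosome-partitioned Parquet
(``CHR=<label>/part-0.parquet``) with JSON sidecars for the cleaning report
and run metadata; a single gzipped TSV is the alternative.  Partitioning by
chromosome keeps region queries to a single partition scan and bounds memory
during meta-analysis, and Parquet round-trips every float bit-exactly.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.dataset as pads
import pyarrow.parquet as pq

#: Canonical output schema, in column order.
SCHEMA_COLUMNS = (
    "RSID", "CHR", "POS_37", "POS_38", "EffectAllele", "OtherAllele",
    "EAF", "EAF_ref", "B", "SE", "Z", "P", "N", "CaseN", "ControlN", "INFO",
    "indel", "multi_allelic", "freq_diff", "strand_flipped", "eaf_imputed",
)

_STRING_COLS = ("RSID", "CHR", "EffectAllele", "OtherAllele")
_INT_COLS = ("POS_37", "POS_38")
_FLAG_COLS = ("indel", "multi_allelic", "freq_diff", "strand_flipped", "eaf_imputed")
_FLOAT_COLS = tuple(
    c for c in SCHEMA_COLUMNS if c not in _STRING_COLS + _INT_COLS + _FLAG_COLS
)

_PARTITIONING = pads.partitioning(pa.schema([("CHR", pa.string())]), flavor="hive")


class StorageError(ValueError):
    """Fatal dataset I/O problem."""


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce to the canonical schema: add absent columns as missing, order, type."""
    out = df.copy()
    for c in SCHEMA_COLUMNS:
        if c not in out.columns:
            out[c] = pd.NA
    for c in _STRING_COLS:
        out[c] = out[c].astype("string")
    for c in _INT_COLS:
        out[c] = out[c].astype("Int64")
    for c in _FLOAT_COLS:
        out[c] = pd.to_numeric(out[c], errors="coerce").astype("float64")
    for c in _FLAG_COLS:
        out[c] = out[c].astype("boolean")
    return out[list(SCHEMA_COLUMNS)].reset_index(drop=True)


@dataclass
class CleanedDataset:
    """Handle to one harmonized dataset on disk."""

    path: Path
    output_format: str  # "hivestyle" | "tsv"

    @property
    def name(self) -> str:
        return self.path.name

    def dataset(self) -> pads.Dataset:
        if self.output_format != "hivestyle":
            raise StorageError("lazy scans require the hivestyle format")
        return pads.dataset(self.path / "data", format="parquet",
                            partitioning=_PARTITIONING)

    def chromosomes(self) -> list[str]:
        meta = self.metadata()
        return list(meta.get("chromosomes", []))

    def read(self) -> pd.DataFrame:
        """Materialize the full table in canonical column order."""
        if self.output_format == "hivestyle":
            df = self.dataset().to_table().to_pandas()
        else:
            df = pd.read_csv(self.path / "data.tsv.gz", sep="\t",
                             na_values=["NA"], keep_default_na=False,
                             dtype={"CHR": str}, float_precision="round_trip")
            for c in _FLAG_COLS:
                df[c] = df[c].map({"True": True, "False": False, True: True, False: False})
        return canonicalize(df)

    def report(self) -> dict:
        return json.loads((self.path / "cleaning_report.json").read_text())

    def metadata(self) -> dict:
        p = self.path / "metadata.json"
        return json.loads(p.read_text()) if p.exists() else {}


def write_output(
    tbl: pd.DataFrame,
    path: str | Path,
    output_format: str = "hivestyle",
    overwrite: bool = False,
    report: "object | None" = None,
    metadata: dict | None = None,
) -> CleanedDataset:
    """Write a harmonized table plus sidecars; returns a dataset handle.

    ``hivestyle`` writes one Parquet partition per chromosome under ``data/``;
    ``tsv`` writes a single ``data.tsv.gz`` with "NA" for missing.  A
    non-empty existing ``path`` is fatal unless ``overwrite`` is set.
    """
    if output_format not in ("hivestyle", "tsv"):
        raise StorageError(f"unknown output_format {output_format!r}")
    path = Path(path)
    if path.exists() and any(path.iterdir()):
        if not overwrite:
            raise StorageError(f"output path exists and is non-empty: {path} "
                               "(pass overwrite=True to replace)")
        shutil.rmtree(path)
    path.mkdir(parents=True, exist_ok=True)

    df = canonicalize(tbl)
    chroms = sorted(df["CHR"].dropna().unique().tolist())
    if output_format == "hivestyle":
        table = pa.Table.from_pandas(df, preserve_index=False)
        pads.write_dataset(
            table, path / "data", format="parquet", partitioning=_PARTITIONING,
            basename_template="part-{i}.parquet",
            existing_data_behavior="overwrite_or_ignore",
        )
    else:
        df.to_csv(path / "data.tsv.gz", sep="\t", index=False, na_rep="NA",
                  float_format="%.17g",  # shortest-round-trip is not guaranteed by default
                  compression={"method": "gzip", "mtime": 0})

    meta = dict(metadata or {})
    meta.setdefault("rows", int(len(df)))
    meta.setdefault("chromosomes", chroms)
    meta.setdefault("output_format", output_format)
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    if report is not None:
        rep = report.to_dict() if hasattr(report, "to_dict") else dict(report)
        (path / "cleaning_report.json").write_text(json.dumps(rep, indent=2))
    return CleanedDataset(path=path, output_format=output_format)


def open_dataset(path: str | Path) -> CleanedDataset:
    """Open a previously written dataset, inferring its format."""
    path = Path(path)
    if (path / "data").is_dir():
        return CleanedDataset(path=path, output_format="hivestyle")
    if (path / "data.tsv.gz").exists():
        return CleanedDataset(path=path, output_format="tsv")
    raise StorageError(f"not a harmonized dataset directory: {path}")


def query_region(
    datasets: Sequence[CleanedDataset | str | Path],
    chrom: str,
    start: int,
    end: int,
    build: int | str = 38,
    p_max: float | None = None,
) -> pd.DataFrame:
    """Rows with CHR == chrom and start <= POS_build <= end across datasets.

    The interval is 1-based closed.  Only the matching chromosome partitions
    are scanned.  A ``dataset`` column identifies the source of each row.
    """
    if str(build) not in ("37", "38"):
        raise StorageError(f"unknown genome build {build!r}; use 37 or 38")
    if start > end:
        raise StorageError(f"region start {start} exceeds end {end}")
    pos_col = f"POS_{build}"
    handles = [d if isinstance(d, CleanedDataset) else open_dataset(d) for d in datasets]
    frames = []
    for h in handles:
        flt = (
            (pads.field("CHR") == str(chrom))
            & (pads.field(pos_col) >= int(start))
            & (pads.field(pos_col) <= int(end))
        )
        if p_max is not None:
            flt = flt & (pads.field("P") <= float(p_max))
        df = h.dataset().to_table(filter=flt).to_pandas()
        df = canonicalize(df)
        df.insert(0, "dataset", h.name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["dataset"] = out["dataset"].astype("string")
    return out
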