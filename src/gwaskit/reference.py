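"""Curated dual-build variant reference: curation filters, normalization, storage.

The reference panel plays the role of a curated dbSNP extract: one record per
variant with its rsID number, chromosome, 1-based positions on both GRCh37 and
GRCh38, the reference allele and one or more alternate alleles, plus a map of
retired ("merged") rsIDs to their current identifiers.  Harmonization merges
summary statistics against this panel to repair variant identity.

Curation applies four filters, in order:

1. remove rsIDs that map to more than one position (on either build);
2. among records sharing a chromosome+position, keep the smallest rsID number
   and remove the rest;
3. remove records whose chromosome differs between GRCh37 and GRCh38;
4. keep only records with positions on both builds.

On disk the panel is hive-partitioned Parquet (``CHR=<label>/``) with SNVs and
left-aligned/trimmed indels in separate partitions, plus a merged-rsID table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pyarrow as pa
import pyarrow.dataset as pads

from ._util import VALID_CHROMS

logger = logging.getLogger(__name__)

#: Raw (uncurated) record columns expected by :func:`curate_reference`.
RAW_COLUMNS = ("RSID", "CHR_37", "POS_37", "CHR_38", "POS_38", "REF", "ALT")

_PANEL_SCHEMA = pa.schema([
    ("RSID", pa.int64()),
    ("POS_37", pa.int64()),
    ("POS_38", pa.int64()),
    ("REF", pa.string()),
    ("ALT", pa.list_(pa.string())),
])

_PARTITIONING = pads.partitioning(pa.schema([("CHR", pa.string())]), flavor="hive")


class ReferenceError(ValueError):
    """Fatal problem with reference data."""


def left_align_trim(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Minimal (left-aligned, trimmed) representation of an allele pair.

    Shared trailing bases are removed first, then shared leading bases with the
    position advanced accordingly; at least one base is kept in each allele.

    >>> left_align_trim("CAG", "CAGAG", 100)
    ('C', 'CAG', 100)
    >>> left_align_trim("TTC", "TC", 100)
    ('TT', 'T', 100)
    """
    if ref == alt:
        raise ReferenceError(f"ref and alt are identical ({ref!r}): not a variant")
    if not ref or not alt:
        raise ReferenceError("empty allele string")
    # strip shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # strip shared prefix, advancing pos
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return ref, alt, pos


def curate_reference(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four curation filters; return (curated records, removal counts).

    ``raw`` needs columns RSID (int rsID number), CHR_37, POS_37, CHR_38,
    POS_38 (positions nullable), REF, ALT (list of alternate alleles).  The
    curated output collapses the per-build chromosomes into a single ``CHR``
    column (they are identical after filter 3) and has non-null positions on
    both builds.
    """
    missing = set(RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise ReferenceError(f"raw reference records lack columns: {sorted(missing)}")
    df = raw.copy()
    counts: dict[str, int] = {}

    # 1: rsID mapping to multiple positions (on either build) -> remove all
    n0 = len(df)
    for build in ("37", "38"):
        key = df[f"CHR_{build}"].astype("string") + ":" + df[f"POS_{build}"].astype("string")
        nuniq = key.groupby(df["RSID"]).transform("nunique")
        df = df[nuniq <= 1]
    counts["multi_position_rsid"] = n0 - len(df)

    # 2: per chr+pos site (each build), keep the smallest rsID number
    n0 = len(df)
    for build in ("37", "38"):
        sub = df.dropna(subset=[f"CHR_{build}", f"POS_{build}"])
        min_rsid = sub.groupby(
            [f"CHR_{build}", f"POS_{build}"], dropna=True)["RSID"].transform("min")
        keep = df.index.difference(sub.index[sub["RSID"] != min_rsid])
        df = df.loc[keep]
    counts["duplicate_position"] = n0 - len(df)

    # 3: chromosome differs between builds
    n0 = len(df)
    both = df["CHR_37"].notna() & df["CHR_38"].notna()
    df = df[~(both & (df["CHR_37"] != df["CHR_38"]))]
    counts["chromosome_mismatch"] = n0 - len(df)

    # 4: keep entries with positions on both builds
    n0 = len(df)
    df = df.dropna(subset=["POS_37", "POS_38", "CHR_37", "CHR_38"])
    counts["missing_build_position"] = n0 - len(df)

    if len(df) == 0:
        logger.warning("curation produced an empty reference panel")

    out = pd.DataFrame({
        "RSID": df["RSID"].astype("int64"),
        "CHR": df["CHR_38"].astype("string"),
        "POS_37": df["POS_37"].astype("int64"),
        "POS_38": df["POS_38"].astype("int64"),
        "REF": df["REF"].astype("string"),
        "ALT": df["ALT"],
    }).reset_index(drop=True)
    return out, counts


def resolve_merged(merged: pd.DataFrame) -> pd.DataFrame:
    """Resolve merge chains (old -> ... -> terminal) to single hops.

    ``merged`` has columns OLD_RSID, NEW_RSID.  dbSNP merges chain across
    releases; every OLD_RSID is mapped transitively to its terminal id.

    Raises on cycles or self-maps.
    """
    mapping = dict(zip(merged["OLD_RSID"].astype(int), merged["NEW_RSID"].astype(int)))
    resolved: dict[int, int] = {}
    for old in mapping:
        if mapping[old] == old:
            raise ReferenceError(f"merged-rsID map sends rs{old} to itself")
        seen = {old}
        cur = mapping[old]
        while cur in mapping:
            if cur in seen:
                raise ReferenceError(f"cycle in merged-rsID map at rs{cur}")
            seen.add(cur)
            cur = mapping[cur]
        if cur == old:
            raise ReferenceError(f"merged-rsID map sends rs{old} to itself")
        resolved[old] = cur
    return pd.DataFrame(
        {"OLD_RSID": list(resolved), "NEW_RSID": list(resolved.values())},
        dtype="int64",
    )


def _write_partitioned(df: pd.DataFrame, path: Path) -> None:
    tbl = pa.Table.from_pandas(
        df[["RSID", "POS_37", "POS_38", "REF", "ALT", "CHR"]], preserve_index=False)
    cast = tbl.cast(pa.schema(list(_PANEL_SCHEMA) + [pa.field("CHR", pa.string())]))
    pads.write_dataset(
        cast, path, format="parquet", partitioning=_PARTITIONING,
        basename_template="part-{i}.parquet", existing_data_behavior="overwrite_or_ignore",
    )


def write_reference(
    snvs: pd.DataFrame,
    path: str | Path,
    merged: pd.DataFrame | None = None,
    indels: pd.DataFrame | None = None,
) -> "ReferencePanel":
    """Persist a curated panel (SNV and optional indel partitions + merged map)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_partitioned(snvs, path / "snv")
    if indels is not None and len(indels):
        _write_partitioned(indels, path / "indel")
    if merged is None:
        merged = pd.DataFrame({"OLD_RSID": pd.Series(dtype="int64"),
                               "NEW_RSID": pd.Series(dtype="int64")})
    pa_merged = pa.Table.from_pandas(merged, preserve_index=False)
    import pyarrow.parquet as pq

    pq.write_table(pa_merged, path / "merged_rsids.parquet")
    meta = {
        "chromosomes": sorted(set(snvs["CHR"].astype(str))),
        "n_snvs": int(len(snvs)),
        "n_indels": int(0 if indels is None else len(indels)),
    }
    (path / "panel.json").write_text(json.dumps(meta, indent=2))
    return load_reference(path)


@dataclass
class ReferencePanel:
    """Lazy handle over a partitioned reference panel on disk."""

    path: Path
    merged: pd.DataFrame  # OLD_RSID -> NEW_RSID, chains resolved
    has_indels: bool
    chromosomes: tuple[str, ...]

    def _dataset(self, kind: str) -> pads.Dataset:
        return pads.dataset(self.path / kind, format="parquet", partitioning=_PARTITIONING)

    def scan(self, chrom: str | None = None, kind: str = "snv") -> pd.DataFrame:
        """Materialize one chromosome (or the whole panel) of one partition kind.

        ``kind``: "snv", "indel" or "both".
        """
        kinds = ("snv", "indel") if kind == "both" else (kind,)
        frames = []
        for k in kinds:
            if k == "indel" and not self.has_indels:
                continue
            dset = self._dataset(k)
            flt = pads.field("CHR") == str(chrom) if chrom is not None else None
            frames.append(dset.to_table(filter=flt).to_pandas())
        if not frames:
            return pd.DataFrame(columns=["RSID", "POS_37", "POS_38", "REF", "ALT", "CHR"])
        out = pd.concat(frames, ignore_index=True)
        out["CHR"] = out["CHR"].astype("string")
        out["REF"] = out["REF"].astype("string")
        return out

    def lookup_rsids(self, rsid_nums: pd.Series, kind: str = "both") -> pd.DataFrame:
        """Fetch panel records for a set of rsID numbers (panel-wide scan, pruned)."""
        uniq = pd.Series(rsid_nums).dropna().astype("int64").unique()
        if len(uniq) == 0:
            return pd.DataFrame(columns=["RSID", "POS_37", "POS_38", "REF", "ALT", "CHR"])
        wanted = pa.array(uniq, type=pa.int64())
        kinds = ("snv", "indel") if kind == "both" else (kind,)
        frames = []
        for k in kinds:
            if k == "indel" and not self.has_indels:
                continue
            tbl = self._dataset(k).to_table(filter=pads.field("RSID").isin(wanted))
            frames.append(tbl.to_pandas())
        out = pd.concat(frames, ignore_index=True)
        out["CHR"] = out["CHR"].astype("string")
        out["REF"] = out["REF"].astype("string")
        return out

    def resolve_rsid(self, rsid_nums: pd.Series) -> pd.Series:
        """Map retired rsID numbers to current ones; unmerged ids pass through."""
        if len(self.merged) == 0:
            return rsid_nums
        m = self.merged.set_index("OLD_RSID")["NEW_RSID"]
        out = rsid_nums.map(m)
        return out.fillna(rsid_nums).astype(rsid_nums.dtype)


def load_reference(path: str | Path) -> ReferencePanel:
    """Open a panel directory written by :func:`write_reference`.

    Never materializes the whole panel; per-chromosome scans read only the
    matching ``CHR=<label>/`` partition.
    """
    path = Path(path)
    if not path.is_dir() or not (path / "snv").is_dir():
        raise ReferenceError(f"not a reference panel directory: {path}")
    meta_path = path / "panel.json"
    if not meta_path.exists():
        raise ReferenceError(f"reference panel missing metadata sidecar: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for chrom in meta["chromosomes"]:
        part = path / "snv" / f"CHR={chrom}"
        if not part.is_dir():
            raise ReferenceError(f"reference panel missing partition: {part}")
    import pyarrow.parquet as pq

    merged_raw = pq.read_table(path / "merged_rsids.parquet").to_pandas()
    merged = resolve_merged(merged_raw) if len(merged_raw) else merged_raw
    return ReferencePanel(
        path=path,
        merged=merged,
        has_indels=(path / "indel").is_dir(),
        chromosomes=tuple(str(c) for c in meta["chromosomes"]),
    )
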