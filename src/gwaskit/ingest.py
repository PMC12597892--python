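"""Parse summary-statistics files and map heterogeneous headers to canonical names.

Summary statistics are shared as delimited text with no agreed column naming:
the effect-size column alone appears in the wild as ``beta``, ``b``, ``Effect``
or ``BETA``.  This module reads any tab/comma/semicolon/whitespace-delimited
file (optionally gzipped), keeps every cell as text (numeric coercion happens
later, during validation), and maps headers onto a fixed canonical vocabulary
via a case-insensitive alias dictionary.  Columns that cannot be mapped, or
that are entirely missing, are dropped and logged.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._util import MISSING_TOKENS, is_missing

logger = logging.getLogger(__name__)

#: Canonical column vocabulary, in output order.
CANONICAL_COLUMNS = (
    "RSID", "CHR", "POS", "EffectAllele", "OtherAllele",
    "B", "SE", "Z", "P", "EAF", "N", "CaseN", "ControlN", "INFO",
)

# Alias dictionary (all lookups lower-cased). Canonical names are their own
# aliases so that an already-canonical header maps to itself.
_ALIASES: dict[str, tuple[str, ...]] = {
    "RSID": ("rsid", "snp", "rs_id", "markername", "variant_id", "id"),
    "CHR": ("chr", "chromosome", "chrom", "#chrom"),
    "POS": ("pos", "bp", "position", "base_pair_location"),
    "EffectAllele": ("effectallele", "a1", "effect_allele", "ea", "alt", "allele1"),
    "OtherAllele": ("otherallele", "a2", "other_allele", "oa", "ref", "nea",
                    "allele2", "allele0"),
    "B": ("b", "beta", "effect"),
    "SE": ("se", "standard_error", "stderr"),
    "Z": ("z", "zscore", "z_score"),
    "P": ("p", "pval", "p_value", "p.value"),
    "EAF": ("eaf", "af", "effect_allele_frequency", "frq", "freq"),
    "N": ("n", "sample_size", "nmiss"),
    "CaseN": ("casen", "n_cases", "ncas"),
    "ControlN": ("controln", "n_controls", "ncon"),
    "INFO": ("info", "imputation_quality", "r2"),
}

ALIAS_LOOKUP: dict[str, str] = {
    alias: canonical for canonical, aliases in _ALIASES.items() for alias in aliases
}

# MAF is accepted as EAF only when nothing else claims EAF; MAF != EAF in
# general, so the fallback is logged.
_MAF_ALIASES = ("maf", "minor_allele_frequency")

_DELIMITERS: tuple[str | None, ...] = ("\t", ",", ";", None)  # None = whitespace


class IngestError(ValueError):
    """Fatal problem reading or mapping an input table."""


@dataclass
class RawTable:
    """A parsed summary-statistics table, all cells as text."""

    df: pd.DataFrame
    source: str
    dropped_all_missing: list[str] = field(default_factory=list)

    @property
    def headers(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)


@dataclass
class ColumnMapping:
    """Original-to-canonical header mapping plus the unmapped remainder."""

    pairs: dict[str, str]
    dropped: list[str]

    def canonical(self) -> set[str]:
        return set(self.pairs.values())


def _open_text(path: Path) -> io.TextIOBase:
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def detect_delimiter(lines: Sequence[str]) -> str | None:
    """Pick the delimiter yielding a constant row width > 1 across ``lines``.

    Candidates are tried in priority order (tab, comma, semicolon, whitespace);
    ``None`` denotes any-whitespace splitting.
    """
    best: str | None = None
    for cand in _DELIMITERS:
        widths = {
            len(line.split(cand) if cand is None else next(csv.reader([line], delimiter=cand)))
            for line in lines
            if line.strip()
        }
        if len(widths) == 1 and widths.pop() > 1:
            return cand
    return best


def parse_input(source: str | os.PathLike | pd.DataFrame) -> RawTable:
    """Read a delimited file (or accept an in-memory table) as all-text cells.

    The delimiter is auto-detected among tab, comma, semicolon and whitespace;
    gzip compression is transparent. A header row is mandatory.

    Raises
    ------
    IngestError
        If the file does not exist, cannot be parsed, or has zero data rows.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.columns = [str(c).strip() for c in df.columns]
        df = df.astype("string")
        if len(df) == 0:
            raise IngestError("in-memory table has zero data rows")
        return RawTable(df=df, source="<in-memory>")

    path = Path(source)
    if not path.exists():
        raise IngestError(f"input file does not exist: {path}")
    try:
        with _open_text(path) as fh:
            head_lines = []
            for _ in range(50):
                line = fh.readline()
                if not line:
                    break
                head_lines.append(line.rstrip("\r\n"))
    except OSError as exc:
        raise IngestError(f"cannot read input file {path}: {exc}") from exc
    if not head_lines:
        raise IngestError(f"input file is empty: {path}")

    delim = detect_delimiter(head_lines)
    sep = r"\s+" if delim is None else delim
    with open(path, "rb") as fh:
        compression = "gzip" if fh.read(2) == b"\x1f\x8b" else None
    df = pd.read_csv(
        path, sep=sep, dtype="string", keep_default_na=False,
        compression=compression, engine="python" if delim is None else "c",
    )
    df.columns = [str(c).strip() for c in df.columns]
    # canonicalize the missing tokens to <NA> up-front
    for col in df.columns:
        df[col] = df[col].where(~df[col].str.strip().isin(MISSING_TOKENS))
    if len(df) == 0:
        raise IngestError(f"input file has zero data rows: {path}")
    return RawTable(df=df, source=str(path))


def guess_names(
    headers: Sequence[str],
    overrides: Mapping[str, str] | None = None,
) -> ColumnMapping:
    """Map original headers to canonical names via case-insensitive alias lookup.

    ``overrides`` (original -> canonical) take precedence over guessing and may
    be partial; an explicit full mapping disables guessing for the named
    columns entirely.

    Raises
    ------
    IngestError
        If two headers resolve to the same canonical name, or ``headers`` is
        empty, or an override names an unknown canonical column.
    """
    if not headers:
        raise IngestError("empty header list")
    overrides = dict(overrides or {})
    for orig, canon in overrides.items():
        if canon not in CANONICAL_COLUMNS:
            raise IngestError(f"override maps {orig!r} to unknown canonical column {canon!r}")

    pairs: dict[str, str] = {}
    assigned: dict[str, str] = {}  # canonical -> original
    dropped: list[str] = []
    maf_headers: list[str] = []

    for h in headers:
        key = h.strip().lower()
        if h in overrides:
            canon = overrides[h]
        elif key in ALIAS_LOOKUP:
            canon = ALIAS_LOOKUP[key]
        elif key in _MAF_ALIASES:
            maf_headers.append(h)
            continue
        else:
            dropped.append(h)
            continue
        if canon in assigned:
            raise IngestError(
                f"headers {assigned[canon]!r} and {h!r} both map to canonical column {canon}"
            )
        assigned[canon] = h
        pairs[h] = canon

    for h in maf_headers:
        if "EAF" not in assigned:
            logger.warning(
                "treating %r as EAF: no effect-allele-frequency column found "
                "(note MAF is not EAF for effect alleles that are major)", h)
            assigned["EAF"] = h
            pairs[h] = "EAF"
        else:
            dropped.append(h)

    return ColumnMapping(pairs=pairs, dropped=dropped)


def select_correct_columns(tbl: RawTable, mapping: ColumnMapping) -> RawTable:
    """Keep only mapped columns, renamed to canonical names.

    Columns whose cells are entirely missing are dropped too (and recorded in
    ``dropped_all_missing``); dropping is logged, never fatal.
    """
    missing_from_tbl = set(mapping.pairs) - set(tbl.headers)
    if missing_from_tbl:
        raise IngestError(f"mapping refers to absent columns: {sorted(missing_from_tbl)}")
    df = tbl.df[list(mapping.pairs)].rename(columns=mapping.pairs)
    dropped_missing = [c for c in df.columns if is_missing(df[c]).all()]
    if dropped_missing:
        logger.warning("dropping all-missing columns: %s", dropped_missing)
        df = df.drop(columns=dropped_missing)
    if mapping.dropped:
        logger.info("dropped unmapped columns: %s", mapping.dropped)
    order = [c for c in CANONICAL_COLUMNS if c in df.columns]
    return RawTable(df=df[order], source=tbl.source, dropped_all_missing=dropped_missing)
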