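"""Row-level validation and harmonization prior to reference matching.

Four steps run in order on the canonically-named table:

* ``remove_rows_with_na`` — EffectAllele and OtherAllele are always required;
  additionally each row needs either an rsID or a complete CHR+POS pair.  When
  CHR, POS *and* RSID are all present the RSID column is dropped wholesale and
  later restored from the reference (input rsIDs are the least trustworthy
  identity source).
* ``remove_duplicates`` — deduplicate on CHR:POS:{allele pair} (or
  RSID:{allele pair} when positions are unavailable); the allele pair is an
  unordered set, so (A,G) and (G,A) at one site collide.
* ``detect_indels`` — flag rows whose alleles are multi-base or use the legacy
  D/I/R codes; strategy decides whether they are matched against the indel
  reference partition ("qc"), passed through unmatched ("keep") or dropped.
* ``validate_columns`` — coerce each column to its proper type, harmonize
  chromosome labels, uppercase alleles, and remove rows with out-of-domain
  values (P outside (0,1], non-positive SE, ...).  Deliberately minimal:
  quality control such as strand-ambiguity or MAF filtering is a downstream
  concern, not harmonization.

Every step accounts for its removals in a :class:`CleaningReport`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import VALID_CHROMS, allele_pair_key, normalize_chr

logger = logging.getLogger(__name__)

#: Report step names, in pipeline order.
REPORT_STEPS = (
    "missing_critical", "duplicates", "indel_dropped", "validation",
    "no_dbsnp_match", "allele_incompatible",
)

#: Largest plausible 1-based position on any human chromosome.
MAX_POS = 300_000_000

#: Smallest positive normal double; substituted for literal P = 0.
TINY_P = float(np.finfo(np.float64).tiny)

_ALLELE_RE = r"^([ACGT]+|[DIR])$"

_NUMERIC_COLUMNS = ("B", "SE", "Z", "P", "EAF", "N", "CaseN", "ControlN", "INFO", "POS")


class CleaningError(ValueError):
    """Fatal validation problem (e.g. a column that is mostly uncoercible)."""


@dataclass
class CleaningReport:
    """Ordered per-step removed-row accounting for one harmonization run."""

    input_rows: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def add(self, step: str, n_removed: int) -> None:
        self.removed[step] = self.removed.get(step, 0) + int(n_removed)

    def note(self, message: str) -> None:
        self.notes.append(message)
        logger.info(message)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def surviving(self) -> int:
        return self.input_rows - self.total_removed

    def to_dict(self) -> dict:
        ordered = {s: self.removed.get(s, 0) for s in REPORT_STEPS}
        for s, n in self.removed.items():  # preserve any extra steps
            ordered.setdefault(s, n)
        return {
            "input_rows": self.input_rows,
            "removed": ordered,
            "surviving_rows": self.surviving(),
            "notes": list(self.notes),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CleaningReport":
        rep = cls(input_rows=d["input_rows"], removed=dict(d["removed"]),
                  notes=list(d.get("notes", [])))
        return rep


def _has_cols(df: pd.DataFrame, *cols: str) -> bool:
    return all(c in df.columns for c in cols)


def remove_rows_with_na(
    df: pd.DataFrame, report: CleaningReport
) -> pd.DataFrame:
    """Drop rows missing critical identity columns; maybe drop the RSID column.

    Raises :class:`CleaningError` if the table offers neither an RSID column
    nor a CHR+POS column pair — variant identity would be unrecoverable.
    """
    if not _has_cols(df, "EffectAllele", "OtherAllele"):
        raise CleaningError("EffectAllele and OtherAllele columns are required")
    # an entirely missing identity column carries no information: treat as absent
    for col in ("RSID", "CHR", "POS"):
        if col in df.columns and df[col].isna().all():
            df = df.drop(columns=[col])
    has_rsid = "RSID" in df.columns
    has_chrpos = _has_cols(df, "CHR", "POS")
    if not has_rsid and not has_chrpos:
        raise CleaningError("table has neither an RSID column nor CHR+POS columns")

    if has_rsid and has_chrpos:
        # reference-derived rsIDs are authoritative; drop and repair later
        df = df.drop(columns=["RSID"])
        has_rsid = False
        report.note("RSID column dropped (CHR, POS and RSID all present); "
                    "rsIDs will be restored from the reference")

    bad = df["EffectAllele"].isna() | df["OtherAllele"].isna()
    rsid_ok = df["RSID"].notna() if has_rsid else pd.Series(False, index=df.index)
    chrpos_ok = (
        (df["CHR"].notna() & df["POS"].notna())
        if has_chrpos else pd.Series(False, index=df.index)
    )
    bad |= ~(rsid_ok | chrpos_ok)
    report.add("missing_critical", int(bad.sum()))
    return df[~bad]


def remove_duplicates(df: pd.DataFrame, report: CleaningReport) -> pd.DataFrame:
    """Deduplicate on variant identity; the first occurrence survives."""
    if _has_cols(df, "CHR", "POS"):
        ident = df["CHR"].astype("string") + ":" + df["POS"].astype("string")
    else:
        ident = df["RSID"].astype("string")
    key = ident + ":" + allele_pair_key(df["EffectAllele"], df["OtherAllele"])
    dup = key.duplicated(keep="first")
    report.add("duplicates", int(dup.sum()))
    return df[~dup]


def detect_indels(
    df: pd.DataFrame, indel_strategy: str = "qc",
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Flag indel rows (multi-base alleles or D/I/R codes) per the strategy.

    "qc" keeps them for matching against the indel reference partition,
    "keep" passes them through unmatched, "drop" removes them.
    """
    if indel_strategy not in ("qc", "keep", "drop"):
        raise CleaningError(f"unknown indel_strategy: {indel_strategy!r}")
    ea = df["EffectAllele"].astype("string").str.upper()
    oa = df["OtherAllele"].astype("string").str.upper()
    is_indel = (
        (ea.str.len() > 1) | (oa.str.len() > 1)
        | ea.isin(["D", "I", "R"]) | oa.isin(["D", "I", "R"])
    ).fillna(False)
    df = df.copy()
    df["indel"] = is_indel.astype("boolean")
    if indel_strategy == "drop":
        if report is not None:
            report.add("indel_dropped", int(is_indel.sum()))
        df = df[~is_indel]
    elif report is not None:
        report.add("indel_dropped", 0)
    return df


def _coerce_numeric(df: pd.DataFrame, col: str, report: CleaningReport) -> pd.Series:
    """Coerce a column to float64; >50% uncoercible (of non-missing) is fatal."""
    raw = df[col]
    if pd.api.types.is_numeric_dtype(raw):
        return pd.to_numeric(raw, errors="coerce").astype("float64")
    s = raw.astype("string").str.strip()
    present = s.notna()
    num = pd.to_numeric(s, errors="coerce")
    failed = present & num.isna()
    if present.sum() > 0 and failed.sum() / present.sum() > 0.5:
        raise CleaningError(
            f"column {col!r}: {int(failed.sum())}/{int(present.sum())} values "
            "fail numeric coercion — likely mis-mapped")
    return num.astype("float64")


def validate_columns(
    df: pd.DataFrame, report: CleaningReport
) -> pd.DataFrame:
    """Coerce types, harmonize labels, and remove rows with out-of-domain values.

    Missing values never fail validation (missingness was handled earlier, and
    statistics columns may legitimately be absent); only present-but-invalid
    values remove a row.
    """
    df = df.copy()
    bad = pd.Series(False, index=df.index)

    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        present = (
            df[col].notna() if pd.api.types.is_numeric_dtype(df[col])
            else df[col].astype("string").str.strip().notna()
        )
        num = _coerce_numeric(df, col, report)
        df[col] = num
        bad |= present & num.isna()  # uncoercible cell

    if "CHR" in df.columns:
        chrom = normalize_chr(df["CHR"])
        bad |= chrom.notna() & ~chrom.isin(VALID_CHROMS)
        df["CHR"] = chrom

    for col in ("EffectAllele", "OtherAllele"):
        alle = df[col].astype("string").str.strip().str.upper()
        bad |= alle.notna() & ~alle.str.match(_ALLELE_RE).fillna(False)
        df[col] = alle
    bad |= (df["EffectAllele"] == df["OtherAllele"]).fillna(False)

    def _num(col: str) -> pd.Series | None:
        return df[col] if col in df.columns else None

    if (p := _num("P")) is not None:
        n_zero = int((p == 0).sum())
        if n_zero:
            df.loc[p == 0, "P"] = TINY_P
            report.note(f"{n_zero} rows had P = 0; replaced with the smallest "
                        "positive normal double (underflow artifact)")
            p = df["P"]
        bad |= p.notna() & ((p < 0) | (p > 1) | (p == 0))
    if (eaf := _num("EAF")) is not None:
        bad |= eaf.notna() & ((eaf <= 0) | (eaf >= 1))
    if (se := _num("SE")) is not None:
        bad |= se.notna() & ((se <= 0) | ~np.isfinite(se.fillna(1.0)))
    if (info := _num("INFO")) is not None:
        bad |= info.notna() & ((info < 0) | (info > 1.1))
    for col in ("N", "CaseN", "ControlN"):
        if (v := _num(col)) is not None:
            bad |= v.notna() & (v <= 0)
    if all(c in df.columns for c in ("N", "CaseN", "ControlN")):
        viol = (df["N"] < df["CaseN"] + df["ControlN"]).fillna(False)
        if viol.any():
            report.note(f"{int(viol.sum())} rows have N < CaseN + ControlN "
                        "(logged, not removed)")
    if (pos := _num("POS")) is not None:
        bad |= pos.notna() & ((pos < 1) | (pos > MAX_POS) | (pos != pos.round()))
    for col in ("B", "Z"):
        if (v := _num(col)) is not None:
            bad |= v.notna() & ~np.isfinite(v.fillna(0.0))

    report.add("validation", int(bad.sum()))
    out = df[~bad]
    if "POS" in out.columns:
        out = out.copy()
        out["POS"] = out["POS"].astype("Int64")
    return out
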