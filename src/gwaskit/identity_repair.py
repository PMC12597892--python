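"""Variant-identity repair: genome-build inference and reference merging.

A summary-statistics table identifies variants either by chromosome+position
(on an unknown genome build) or by rsID (possibly retired).  This module

* infers the genome build by matching up to 10,000 rows against the panel's
  GRCh37 and GRCh38 positions and keeping the build with more matches;
* splits compound identifiers (``1:12345:A:G`` and friends) found in the rsID
  column into CHR and POS;
* merges the table with the reference panel — by CHR:POS on the inferred
  build, or by rsID (after updating retired ids through the merged-rsID map) —
  attaching the rsID and positions on *both* builds, and dropping rows with no
  panel entry or with alleles incompatible with the panel's ref/alt set;
* flags multiallelic variants (rows sharing an rsID after repair).

Allele compatibility: the unordered pair {EffectAllele, OtherAllele} must be a
subset of {ref} ∪ alts with one member equal to ref; failing that, the
base-complemented pair may satisfy the same (a strand flip, tolerated and
flagged ``strand_flipped``).  Palindromic pairs (A/T, C/G) match in the
original orientation and are never removed here — strand QC is downstream.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import VALID_CHROMS, complement_allele, normalize_chr
from .cleaning import CleaningReport
from .reference import ReferencePanel

logger = logging.getLogger(__name__)

BUILD_SAMPLE_ROWS = 10_000

_COMPOUND_RE = re.compile(
    r"^(?:chr|ch)?(\d{1,2}|x|y|mt|m)[:_](\d+)(?:[:_]([acgt]+)[:_]([acgt]+))?$",
    re.IGNORECASE,
)


class IdentityError(ValueError):
    """Fatal identity-repair problem (e.g. no overlap with the reference)."""


@dataclass
class BuildCall:
    """Outcome of genome-build inference."""

    build: str  # "GRCh37" or "GRCh38"
    n_sampled: int
    matches_37: int
    matches_38: int

    @property
    def pos_column(self) -> str:
        return "POS_37" if self.build == "GRCh37" else "POS_38"

    def to_dict(self) -> dict:
        return {"build": self.build, "n_sampled": self.n_sampled,
                "matches_37": self.matches_37, "matches_38": self.matches_38}


def infer_build(tbl: pd.DataFrame, panel: ReferencePanel) -> BuildCall:
    """Call the genome build by counting CHR:POS matches against each build.

    The first ``BUILD_SAMPLE_ROWS`` rows (after cleaning) with complete CHR+POS
    are compared; ties break to GRCh38 with a warning.  Zero matches on both
    builds is fatal: the table shares no variants with the reference.
    """
    if not {"CHR", "POS"} <= set(tbl.columns):
        raise IdentityError("build inference requires CHR and POS columns")
    sample = tbl.loc[tbl["CHR"].notna() & tbl["POS"].notna(), ["CHR", "POS"]]
    sample = sample.head(BUILD_SAMPLE_ROWS)
    n = len(sample)
    if n == 0:
        raise IdentityError("no rows with complete CHR and POS for build inference")

    matches = {"37": 0, "38": 0}
    pos = sample["POS"].astype("int64")
    for chrom, grp in sample.groupby(sample["CHR"].astype(str)):
        ref = panel.scan(chrom, kind="both")
        p = pos.loc[grp.index]
        for build in ("37", "38"):
            matches[build] += int(p.isin(set(ref[f"POS_{build}"])).sum())

    if matches["37"] == 0 and matches["38"] == 0:
        raise IdentityError("no overlap with reference on either genome build")
    if matches["37"] > matches["38"]:
        build = "GRCh37"
    else:
        if matches["37"] == matches["38"]:
            warnings.warn("build inference tie; defaulting to GRCh38", stacklevel=2)
        build = "GRCh38"
    return BuildCall(build=build, n_sampled=n,
                     matches_37=matches["37"], matches_38=matches["38"])


def split_compound_ids(tbl: pd.DataFrame) -> pd.DataFrame:
    """Split ``[chr]CHR:POS[:REF:ALT]`` values found in the RSID column.

    Matching rows get CHR and POS filled (creating the columns if necessary)
    and their RSID cell cleared; alleles embedded in the compound id are
    ignored in favor of the allele columns.  Non-matching rows pass through.
    """
    if "RSID" not in tbl.columns:
        return tbl
    df = tbl.copy()
    rs = df["RSID"].astype("string").str.strip()
    parts = rs.str.extract(_COMPOUND_RE)
    hit = parts[0].notna()
    if not hit.any():
        return df
    chrom = normalize_chr(parts.loc[hit, 0])
    pos = pd.to_numeric(parts.loc[hit, 1], errors="coerce").astype("Int64")
    if "CHR" not in df.columns:
        df["CHR"] = pd.Series(pd.NA, index=df.index, dtype="string")
    if "POS" not in df.columns:
        df["POS"] = pd.Series(pd.NA, index=df.index, dtype="Int64")
    df.loc[hit, "CHR"] = chrom
    df.loc[hit, "POS"] = pos
    df.loc[hit, "RSID"] = pd.NA
    logger.info("split %d compound CHR:POS identifiers out of the RSID column",
                int(hit.sum()))
    return df


def _alleles_compatible(
    ea: np.ndarray, oa: np.ndarray, ref: np.ndarray, alts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row compatibility of {ea, oa} with {ref} ∪ alts (strand flip tolerated).

    Returns (compatible, strand_flipped) boolean arrays.
    """
    n = len(ea)
    ok = np.zeros(n, dtype=bool)
    flipped = np.zeros(n, dtype=bool)
    for i in range(n):
        allowed = {ref[i], *alts[i]}
        pair = {ea[i], oa[i]}
        if pair <= allowed and ref[i] in pair:
            ok[i] = True
            continue
        cpair = {complement_allele(ea[i]), complement_allele(oa[i])}
        if cpair <= allowed and ref[i] in cpair:
            ok[i] = True
            flipped[i] = True
    return ok, flipped


def _merge_by_position(
    rows: pd.DataFrame, panel: ReferencePanel, pos_col: str
) -> pd.DataFrame:
    """Attach panel columns by CHR + POS on the inferred build, per chromosome."""
    out = []
    for chrom, grp in rows.groupby(rows["CHR"].astype(str), sort=False):
        # indel rows match the left-aligned indel partition, SNVs the SNV one
        for indel_flag in (False, True):
            sub = grp[grp["indel"].fillna(False).astype(bool) == indel_flag]
            if sub.empty:
                continue
            kind = "indel" if (indel_flag and panel.has_indels) else "snv"
            ref = panel.scan(chrom, kind=kind)
            ref = ref.rename(columns={"RSID": "_panel_rsid", "CHR": "_panel_chr"})
            sub = sub.copy()
            sub["_pos_key"] = sub["POS"].astype("int64")
            if len(ref):
                ref["_pos_key"] = ref[pos_col].astype("int64")
                merged = sub.merge(ref, on="_pos_key", how="left")
            else:
                merged = sub.assign(_panel_rsid=pd.NA, _panel_chr=pd.NA,
                                    POS_37=pd.NA, POS_38=pd.NA, REF=pd.NA, ALT=None)
            out.append(merged.drop(columns="_pos_key"))
    if not out:
        return rows.iloc[0:0].assign(_panel_rsid=pd.NA, _panel_chr=pd.NA,
                                     POS_37=pd.NA, POS_38=pd.NA, REF=pd.NA, ALT=None)
    return pd.concat(out, ignore_index=True)


def repair_ids(
    tbl: pd.DataFrame,
    panel: ReferencePanel,
    build: BuildCall | None,
    report: CleaningReport,
) -> pd.DataFrame:
    """Merge with the reference, restoring rsIDs and both-build positions.

    Rows with complete CHR+POS merge by position on the inferred build; the
    remaining rows with an rsID merge by rsID number after resolving retired
    ids through the merged-rsID map.  Rows with no panel entry are removed
    (``no_dbsnp_match``), as are rows whose allele pair is incompatible with
    the panel's ref/alt set (``allele_incompatible``).  Surviving rows carry
    RSID, CHR, POS_37, POS_38 plus ``strand_flipped`` flags and the panel
    alternate-allele list in ``ALT`` (used for frequency orientation).
    """
    df = tbl.copy()
    if "indel" not in df.columns:
        df["indel"] = pd.Series(False, index=df.index, dtype="boolean")
    has_chrpos = {"CHR", "POS"} <= set(df.columns)
    chrpos_rows = (
        df["CHR"].notna() & df["POS"].notna() if has_chrpos
        else pd.Series(False, index=df.index)
    )
    rsid_rows = ~chrpos_rows
    if "RSID" in df.columns:
        rsid_rows &= df["RSID"].notna()

    merged_parts: list[pd.DataFrame] = []

    if chrpos_rows.any():
        if build is None:
            raise IdentityError("position-based repair requires a build call")
        part = _merge_by_position(df[chrpos_rows], panel, build.pos_column)
        merged_parts.append(part)

    if "RSID" in df.columns and rsid_rows.any():
        sub = df[rsid_rows].copy()
        from ._util import rsid_number

        nums = rsid_number(sub["RSID"])
        nums = panel.resolve_rsid(nums)
        sub["_rsid_num"] = nums
        ref = panel.lookup_rsids(nums, kind="both")
        merged = sub.merge(
            ref.rename(columns={"RSID": "_panel_rsid", "CHR": "_panel_chr"}),
            left_on="_rsid_num", right_on="_panel_rsid", how="left",
        )
        merged["CHR"] = merged["_panel_chr"]
        merged = merged.drop(columns=["_rsid_num"])
        merged_parts.append(merged)

    if not merged_parts:
        raise IdentityError("no rows eligible for identity repair")
    m = pd.concat(merged_parts, ignore_index=True)

    no_match = m["_panel_rsid"].isna()
    report.add("no_dbsnp_match", int(no_match.sum()))
    m = m[~no_match]

    if len(m):
        ok, flipped = _alleles_compatible(
            m["EffectAllele"].astype(str).to_numpy(),
            m["OtherAllele"].astype(str).to_numpy(),
            m["REF"].astype(str).to_numpy(),
            m["ALT"].to_numpy(),
        )
    else:
        ok = np.zeros(0, dtype=bool)
        flipped = ok
    report.add("allele_incompatible", int((~ok).sum()))
    m = m[ok].copy()
    m["strand_flipped"] = pd.array(flipped[ok], dtype="boolean")

    m["RSID"] = "rs" + m["_panel_rsid"].astype("int64").astype(str)
    m["RSID"] = m["RSID"].astype("string")
    m["CHR"] = m["CHR"].where(m["CHR"].notna(), m["_panel_chr"]).astype("string")
    m["POS_37"] = m["POS_37"].astype("int64")
    m["POS_38"] = m["POS_38"].astype("int64")
    drop = [c for c in ("POS", "_panel_rsid", "_panel_chr", "key_0") if c in m.columns]
    return m.drop(columns=drop).reset_index(drop=True)


def flag_multiallelic(tbl: pd.DataFrame) -> pd.DataFrame:
    """Set ``multi_allelic`` true on every row sharing an rsID with another row."""
    df = tbl.copy()
    if len(df) == 0:
        df["multi_allelic"] = pd.Series(dtype="boolean")
        return df
    df["multi_allelic"] = df["RSID"].duplicated(keep=False).astype("boolean")
    return df
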