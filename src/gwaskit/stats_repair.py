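"""Impute missing statistics columns from closed-form identities.

Under the standard approximations for an additive-model GWAS of a quantitative
(or effective-N case-control) trait, the summary-statistics columns are
algebraically linked, which lets missing columns be recovered from present
ones.  The identities, applied in this order and filling only missing cells:

* ``Z = B / SE``                                    (B, SE present)
* ``Z = sign(B) * sqrt(qchisq_upper(P, df=1))``     (B, P present; SE absent)
* ``B = Z / sqrt(2*EAF*(1-EAF) * (N + Z^2))`` and
  ``SE = 1 / sqrt(2*EAF*(1-EAF) * (N + Z^2))``      (Z, N, EAF present)
* ``P = 2 * Phi(-|Z|)``                             (Z present)
* ``N = 4 / (2*MAF*(1-MAF) * SE^2)``, MAF = min(EAF, 1-EAF)
                                                    (SE, EAF present; N absent)

Existing values are never overwritten.  Two passes run so that a fill in one
identity can enable a later one (the dependency graph needs no more).  Rows
where a formula is undefined (EAF of exactly 0/1, non-positive N) are skipped
for that imputation.

The factor 4 in the N identity is the effective-sample-size convention for
case-control designs (N_eff = 4 / (1/N_cases + 1/N_controls)); note it is not
the algebraic inverse of the SE identity at Z = 0, which would carry factor 1.

This module also appends reference allele frequencies from a per-population
frequency table and flags variants whose reported frequency differs from the
reference by more than 0.2.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import complement_allele, rsid_number

logger = logging.getLogger(__name__)

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

#: |EAF - EAF_ref| above this flags a frequency mismatch.
FREQ_DIFF_THRESHOLD = 0.2


class StatsError(ValueError):
    """Fatal statistics-repair problem."""


def z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """|Z| via the upper-tail chi-square(1) quantile of P, signed by ``sign``."""
    return np.sign(sign) * np.sqrt(stats.chi2.isf(p, df=1))


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided P from Z; ``sf`` keeps precision deep into the tail."""
    return 2.0 * stats.norm.sf(np.abs(z))


def _ensure_float(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
        else:
            df[c] = pd.to_numeric(df[c], errors="coerce").astype("float64")
    return df


def repair_stats(tbl: pd.DataFrame) -> pd.DataFrame:
    """Fill missing B, SE, Z, P, N cells from the identities above.

    Cells, not columns, are the unit: a partially missing column is filled
    where its inputs exist.  A fully populated table passes through unchanged.
    """
    df = tbl.copy()
    df = _ensure_float(df, ("B", "SE", "Z", "P", "EAF", "N"))
    n_skipped = 0

    for _ in range(2):  # two passes reach the fixpoint of this dependency graph
        B, SE, Z, P = (df[c].to_numpy() for c in ("B", "SE", "Z", "P"))
        EAF, N = df["EAF"].to_numpy(), df["N"].to_numpy()

        m = np.isnan(Z) & ~np.isnan(B) & ~np.isnan(SE)
        if m.any():
            df.loc[m, "Z"] = B[m] / SE[m]

        Z = df["Z"].to_numpy()
        m = np.isnan(Z) & ~np.isnan(B) & ~np.isnan(P) & np.isnan(SE)
        if m.any():
            df.loc[m, "Z"] = z_from_p(P[m], B[m])

        Z = df["Z"].to_numpy()
        eaf_ok = ~np.isnan(EAF) & (EAF > 0) & (EAF < 1)
        n_ok = ~np.isnan(N) & (N > 0)
        have = ~np.isnan(Z) & eaf_ok & n_ok
        denom = np.full_like(Z, np.nan)
        denom[have] = np.sqrt(2.0 * EAF[have] * (1.0 - EAF[have]) * (N[have] + Z[have] ** 2))
        m = np.isnan(B) & have
        if m.any():
            df.loc[m, "B"] = Z[m] / denom[m]
        m = np.isnan(SE) & have
        if m.any():
            df.loc[m, "SE"] = 1.0 / denom[m]
        bad = ~np.isnan(Z) & (np.isnan(B) | np.isnan(SE)) & ~have & (
            (~np.isnan(EAF) & ~eaf_ok) | (~np.isnan(N) & ~n_ok))
        n_skipped += int(bad.sum())

        Z, P = df["Z"].to_numpy(), df["P"].to_numpy()
        m = np.isnan(P) & ~np.isnan(Z)
        if m.any():
            df.loc[m, "P"] = p_from_z(Z[m])

        SE = df["SE"].to_numpy()
        maf = np.minimum(EAF, 1.0 - EAF)
        m = np.isnan(N) & ~np.isnan(SE) & eaf_ok
        if m.any():
            df.loc[m, "N"] = 4.0 / ((2.0 * maf[m] * (1.0 - maf[m])) * SE[m] ** 2)

    if n_skipped:
        logger.warning("%d rows skipped an imputation (EAF at 0/1 or N <= 0)",
                       n_skipped)
    return df


def load_frequency_reference(path: str | Path) -> pd.DataFrame:
    """Read a per-population frequency table (RSID, ALT, one column per population)."""
    import pyarrow.parquet as pq

    df = pq.read_table(Path(path)).to_pandas()
    required = {"RSID", "ALT"}
    if not required <= set(df.columns):
        raise StatsError(f"frequency reference lacks columns {sorted(required - set(df.columns))}")
    return df


def append_reference_freq(
    tbl: pd.DataFrame, freq_ref: pd.DataFrame, population: str
) -> pd.DataFrame:
    """Attach ``EAF_ref``: the reference frequency oriented to the effect allele.

    ``freq_ref`` carries the alternate-allele frequency; when the row's effect
    allele is the panel reference allele the complement ``1 - freq`` applies.
    Rows missing their own EAF are filled from ``EAF_ref`` and flagged
    ``eaf_imputed``.  Variants absent from the reference keep a missing
    ``EAF_ref``.
    """
    if population not in POPULATIONS:
        raise StatsError(f"unknown population {population!r}; choose from {POPULATIONS}")
    if population not in freq_ref.columns:
        raise StatsError(f"frequency reference has no column for population {population!r}")
    df = tbl.copy()
    ref = freq_ref[["RSID", "ALT", population]].rename(
        columns={"RSID": "_fr_rsid", "ALT": "_fr_alt", population: "_fr_freq"})
    df["_rsid_num"] = rsid_number(df["RSID"])
    df = df.merge(ref, left_on="_rsid_num", right_on="_fr_rsid", how="left")

    ea = df["EffectAllele"].astype(str)
    alt = df["_fr_alt"].astype(str)
    ea_is_alt = (ea == alt) | (ea.map(complement_allele) == alt)
    freq = pd.to_numeric(df["_fr_freq"], errors="coerce")
    df["EAF_ref"] = np.where(ea_is_alt, freq, 1.0 - freq)
    df.loc[freq.isna(), "EAF_ref"] = np.nan

    if "EAF" not in df.columns:
        df["EAF"] = np.nan
    df["EAF"] = pd.to_numeric(df["EAF"], errors="coerce")
    fill = df["EAF"].isna() & df["EAF_ref"].notna()
    df["eaf_imputed"] = pd.array(fill, dtype="boolean")
    df.loc[fill, "EAF"] = df.loc[fill, "EAF_ref"]
    if fill.any():
        logger.info("filled EAF from reference frequencies for %d rows", int(fill.sum()))
    return df.drop(columns=["_rsid_num", "_fr_rsid", "_fr_alt", "_fr_freq"])


def add_freq_diff_flag(
    tbl: pd.DataFrame,
    freq_ref: pd.DataFrame | None = None,
    population: str | None = None,
) -> pd.DataFrame:
    """Flag rows whose |EAF - EAF_ref| exceeds 0.2.

    If ``EAF_ref`` is not yet attached, ``freq_ref`` and ``population`` are
    used to attach it first.  Rows lacking either frequency get a missing flag
    (not false); no rows are removed.
    """
    df = tbl
    if "EAF_ref" not in df.columns:
        if freq_ref is None or population is None:
            raise StatsError("EAF_ref absent: a frequency reference and population are required")
        df = append_reference_freq(df, freq_ref, population)
    df = df.copy()
    eaf = pd.to_numeric(df.get("EAF"), errors="coerce")
    ref = pd.to_numeric(df["EAF_ref"], errors="coerce")
    diff = (eaf - ref).abs()
    flag = pd.array(diff > FREQ_DIFF_THRESHOLD, dtype="boolean")
    flag[diff.isna().to_numpy()] = pd.NA
    df["freq_diff"] = flag
    return df
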