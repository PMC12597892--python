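"""Small shared helpers: missing-value tokens, chromosome normalization, complements."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: String tokens treated as missing in raw summary-statistics files.
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", ".", "N/A", "null"})

#: Chromosome labels accepted after normalization.
VALID_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

# PLINK-style numeric aliases for the sex/mito chromosomes.
_CHR_NUMERIC_ALIASES = {"23": "X", "24": "Y", "25": "MT", "M": "MT"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def is_missing(series: pd.Series) -> pd.Series:
    """Boolean mask of missing cells in a string-typed column."""
    return series.isna() | series.astype("string").str.strip().isin(MISSING_TOKENS)


def normalize_chr(series: pd.Series) -> pd.Series:
    """Map "chr1"/"ch1"/"CHR1"/"1" to "1", "23"->"X", "24"->"Y", "25"/"M"->"MT".

    Unrecognized labels are returned as-is (uppercased, prefix-stripped) so the
    caller can decide to drop them.
    """
    s = series.astype("string").str.strip().str.upper()
    s = s.str.replace(r"^CHR|^CH", "", regex=True)
    # "1.0" from float-parsed chromosome columns
    s = s.str.replace(r"\.0$", "", regex=True)
    return s.replace(_CHR_NUMERIC_ALIASES)


def complement_allele(allele: str) -> str:
    """Base-complement of an allele string (per-base; D/I/R codes unchanged)."""
    if allele in ("D", "I", "R"):
        return allele
    return allele.translate(_COMPLEMENT)


def allele_pair_key(ea: pd.Series, oa: pd.Series) -> pd.Series:
    """Order-independent key for an allele pair ("A|G" for both A/G and G/A)."""
    ea = ea.astype("string")
    oa = oa.astype("string")
    lo = ea.where(ea <= oa, oa)
    hi = oa.where(ea <= oa, ea)
    return lo + "|" + hi


def rsid_number(series: pd.Series) -> pd.Series:
    """Extract the integer part of rsID strings; non-conforming values -> <NA>."""
    num = series.astype("string").str.strip().str.extract(r"^rs(\d+)$", expand=False)
    return pd.to_numeric(num, errors="coerce").astype("Int64")


def as_float(series: pd.Series) -> np.ndarray:
    """Nullable-to-float64 view with NaN for missing."""
    return series.astype("float64").to_numpy()
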