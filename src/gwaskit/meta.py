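"""Fixed-effects inverse-variance meta-analysis over harmonized datasets.

Studies are pooled per variant with inverse-variance weights ``w_i = 1/SE_i^2``:

    B_meta  = sum(w_i * B_i) / sum(w_i)
    SE_meta = 1 / sqrt(sum(w_i))
    Z_meta  = B_meta / SE_meta,   P_meta = 2 * Phi(-|Z_meta|)

with Cochran's heterogeneity statistic and its derived quantities

    Q      = sum(w_i * (B_i - B_meta)^2)
    P_het  = upper tail of chi-square(k - 1) at Q
    I^2    = max(0, (Q - (k - 1)) / Q) * 100 %

Variants are grouped by rsID; within a group the first study's allele
orientation is canonical, a study with swapped alleles contributes ``-B_i``
(and complemented EAF), and a study whose allele set does not match is
excluded and marked "?" in the per-study direction string.  Processing is
per chromosome partition, so memory stays bounded by one chromosome of the
combined studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .storage import CleanedDataset, open_dataset

logger = logging.getLogger(__name__)

_REQUIRED = ("RSID", "CHR", "POS_37", "POS_38", "EffectAllele", "OtherAllele", "B", "SE")

#: Output columns of one pooled variant.
META_COLUMNS = (
    "RSID", "CHR", "POS_37", "POS_38", "EffectAllele", "OtherAllele",
    "k", "B_meta", "SE_meta", "Z_meta", "P_meta",
    "Q", "P_het", "I2", "N_total", "direction",
)


class MetaError(ValueError):
    """Fatal meta-analysis input problem."""


@dataclass
class StudyEffect:
    """One study's aligned contribution to a variant."""

    study: int
    B: float
    SE: float
    N: float | None = None

    @property
    def w(self) -> float:
        return 1.0 / (self.SE * self.SE)


def align_effects(rows: pd.DataFrame) -> tuple[list[StudyEffect], list[str]]:
    """Align per-study rows of one variant to the first row's allele orientation.

    Returns the usable study effects and the per-row direction characters
    ("+", "-", "?").  Rows with a swapped allele pair contribute ``-B``; rows
    whose allele set differs are excluded with "?".
    """
    ea0 = rows["EffectAllele"].iloc[0]
    oa0 = rows["OtherAllele"].iloc[0]
    effects: list[StudyEffect] = []
    direction: list[str] = []
    for _, r in rows.iterrows():
        b, se = r["B"], r["SE"]
        if pd.isna(b) or pd.isna(se) or se <= 0:
            direction.append("?")
            continue
        if (r["EffectAllele"], r["OtherAllele"]) == (ea0, oa0):
            b_al = float(b)
        elif (r["EffectAllele"], r["OtherAllele"]) == (oa0, ea0):
            b_al = -float(b)
        else:
            direction.append("?")
            continue
        n = r["N"] if "N" in rows.columns else np.nan
        effects.append(StudyEffect(study=int(r["_study"]) if "_study" in rows.columns else 0,
                                   B=b_al, SE=float(se),
                                   N=float(n) if pd.notna(n) else None))
        direction.append("+" if b_al > 0 else "-" if b_al < 0 else "0")
    return effects, direction


def _pool_chromosome(long: pd.DataFrame, n_studies: int, min_k: int) -> pd.DataFrame:
    """Vectorized IVW pooling of one chromosome's long (study-stacked) table."""
    df = long[long["B"].notna() & long["SE"].notna() & (long["SE"] > 0)].copy()
    if df.empty:
        return pd.DataFrame(columns=META_COLUMNS)

    # canonical orientation = first occurrence (lowest study index) per rsID
    df = df.sort_values(["RSID", "_study"], kind="stable")
    first = df.groupby("RSID", sort=False).first()[["EffectAllele", "OtherAllele"]]
    first = first.rename(columns={"EffectAllele": "_ea0", "OtherAllele": "_oa0"})
    df = df.join(first, on="RSID")

    same = (df["EffectAllele"] == df["_ea0"]) & (df["OtherAllele"] == df["_oa0"])
    swap = (df["EffectAllele"] == df["_oa0"]) & (df["OtherAllele"] == df["_ea0"])
    df["_b"] = np.where(same, df["B"], -df["B"])
    usable = (same | swap).to_numpy()
    df = df[usable]

    w = 1.0 / df["SE"].to_numpy() ** 2
    df["_w"] = w
    df["_wb"] = w * df["_b"].to_numpy()
    g = df.groupby("RSID", sort=False)
    agg = g.agg(
        CHR=("CHR", "first"), POS_37=("POS_37", "first"), POS_38=("POS_38", "first"),
        EffectAllele=("_ea0", "first"), OtherAllele=("_oa0", "first"),
        k=("_w", "size"), sw=("_w", "sum"), swb=("_wb", "sum"),
        N_total=("N", "sum"),
    )
    agg["B_meta"] = agg["swb"] / agg["sw"]
    agg["SE_meta"] = 1.0 / np.sqrt(agg["sw"])
    agg["Z_meta"] = agg["B_meta"] / agg["SE_meta"]
    agg["P_meta"] = 2.0 * stats.norm.sf(np.abs(agg["Z_meta"]))

    df = df.join(agg["B_meta"], on="RSID")
    df["_q"] = df["_w"] * (df["_b"] - df["B_meta"]) ** 2
    agg["Q"] = df.groupby("RSID", sort=False)["_q"].sum()
    k = agg["k"].to_numpy().astype(float)
    q = agg["Q"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        p_het = stats.chi2.sf(q, k - 1)
        i2 = np.maximum(0.0, (q - (k - 1)) / q) * 100.0
    i2 = np.where(q == 0, 0.0, i2)
    single = k < 2
    agg["P_het"] = np.where(single, np.nan, p_het)
    agg["I2"] = np.where(single, np.nan, i2)
    agg.loc[single.astype(bool), "Q"] = np.nan

    # per-study direction string, "?" for absent/unusable studies
    dirs = np.full((len(agg), n_studies), "?", dtype="<U1")
    rs_index = pd.Index(agg.index)
    row_pos = rs_index.get_indexer(df["RSID"])
    ch = np.where(df["_b"].to_numpy() > 0, "+", np.where(df["_b"].to_numpy() < 0, "-", "0"))
    dirs[row_pos, df["_study"].to_numpy()] = ch
    agg["direction"] = ["".join(r) for r in dirs]

    out = agg.reset_index()
    out = out[out["k"] >= min_k]
    return out[list(META_COLUMNS)]


def meta_analyse(
    datasets: Sequence[CleanedDataset | str | Path],
    min_k: int = 2,
    chromosomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pool every variant across >= 2 harmonized datasets, chromosome by chromosome.

    Rows lacking B or SE are skipped per study.  Variants observed in fewer
    than ``min_k`` usable studies are omitted.  Requires hivestyle datasets
    (per-partition processing is the point).
    """
    handles = [d if isinstance(d, CleanedDataset) else open_dataset(d) for d in datasets]
    if len(handles) < 2:
        raise MetaError("meta-analysis needs at least 2 datasets")
    for h in handles:
        if h.output_format != "hivestyle":
            raise MetaError(f"dataset {h.name} is not hivestyle; re-write it as such")
        cols = set(h.dataset().schema.names)
        missing = set(_REQUIRED) - cols
        if missing:
            raise MetaError(f"dataset {h.name} lacks required columns {sorted(missing)}")

    if chromosomes is None:
        chroms: list[str] = sorted({c for h in handles for c in h.chromosomes()})
    else:
        chroms = [str(c) for c in chromosomes]

    results = []
    import pyarrow.dataset as pads

    for chrom in chroms:
        frames = []
        for i, h in enumerate(handles):
            t = h.dataset().to_table(
                columns=["RSID", "CHR", "POS_37", "POS_38", "EffectAllele",
                         "OtherAllele", "B", "SE", "N"],
                filter=pads.field("CHR") == chrom,
            ).to_pandas()
            if len(t):
                t["_study"] = i
                frames.append(t)
        if not frames:
            continue
        long = pd.concat(frames, ignore_index=True)
        pooled = _pool_chromosome(long, n_studies=len(handles), min_k=min_k)
        if len(pooled):
            results.append(pooled)
    if not results:
        return pd.DataFrame(columns=META_COLUMNS)
    out = pd.concat(results, ignore_index=True)
    logger.info("meta-analysis pooled %d variants (mean k = %.2f)",
                len(out), float(out["k"].mean()))
    return out


def to_metal_tsv(results: pd.DataFrame, path: str | Path) -> None:
    """Write pooled results in a METAL-style column layout."""
    out = pd.DataFrame({
        "MarkerName": results["RSID"],
        "Allele1": results["EffectAllele"],
        "Allele2": results["OtherAllele"],
        "Effect": results["B_meta"],
        "StdErr": results["SE_meta"],
        "P-value": results["P_meta"],
        "Direction": results["direction"],
        "HetISq": results["I2"],
        "HetChiSq": results["Q"],
        "HetDf": results["k"] - 1,
        "HetPVal": results["P_het"],
    })
    out.to_csv(Path(path), sep="\t", index=False, na_rep="NA")
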