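"""Deterministic synthetic data: reference panels and raw sumstats with ground truth.

Every pipeline stage is testable offline: this module fabricates (a) a curated
dual-build variant reference of the kind harmonization merges against, with
optional planted curation violations whose per-filter removal counts are known
exactly, and (b) messy raw summary-statistics files drawn from that panel with
a fully known expected harmonized output and per-filter expected removal
counts ("corruption plan").

Statistical columns are simulated self-consistently with the imputation
identities: per variant, EAF ~ Uniform(0.05, 0.95), a true effect
beta ~ Normal(0, 0.02^2) plus unit sampling noise on the Z scale, then

    SE = 1 / sqrt(2 * EAF * (1-EAF) * (N + Z^2)),  B = Z * SE,
    P  = 2 * Phi(-|Z|)

so that deleting any one of Z, B, SE or P and re-imputing it recovers the
ground truth (the N identity uses the effective-N factor-4 convention and is
deliberately not invertible from these quantities).

Corruptions are applied to disjoint row sets by default so each cleaning
filter's removal count is attributable to exactly one plan entry; an overlap
mode exists for filter-ordering experiments.  A single integer seed governs
all randomness; identical specs produce byte-identical outputs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import reference as refmod
from .ingest import _ALIASES
from .reference import ReferencePanel, write_reference

_BASES = np.array(["A", "C", "G", "T"])

#: Default per-chromosome GRCh37 -> GRCh38 position offsets.
_DEFAULT_OFFSET = 10_000


@dataclass(frozen=True)
class CorruptionPlan:
    """Counts of deliberately broken rows to plant in a raw sumstats file."""

    na_rows: int = 0                # blank EffectAllele -> missing_critical
    duplicate_rows: int = 0         # exact copies appended -> duplicates
    invalid_p: int = 0              # P outside (0,1] -> validation
    invalid_eaf: int = 0            # EAF outside (0,1) -> validation
    invalid_se: int = 0             # SE <= 0 -> validation
    off_panel: int = 0              # positions absent from panel -> no_dbsnp_match
    allele_incompatible: int = 0    # alleles clash with panel -> allele_incompatible
    compound_ids: int = 0           # rsID cell rewritten as CHR:POS:REF:ALT (survives)
    chr_prefixed: int = 0           # CHR written as "chr<label>" (survives)
    swapped_alleles: int = 0        # EA/OA swapped, B negated, EAF complemented (survives)

    def total_removed(self) -> int:
        return (self.na_rows + self.duplicate_rows + self.invalid_p
                + self.invalid_eaf + self.invalid_se + self.off_panel
                + self.allele_incompatible)

    def expected_report(self) -> dict[str, int]:
        return {
            "missing_critical": self.na_rows,
            "duplicates": self.duplicate_rows,
            "indel_dropped": 0,
            "validation": self.invalid_p + self.invalid_eaf + self.invalid_se,
            "no_dbsnp_match": self.off_panel,
            "allele_incompatible": self.allele_incompatible,
        }


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study (panel + sumstats)."""

    seed: int = 0
    n_variants: int = 1000
    chromosomes: tuple[str, ...] = ("1", "2", "3")
    build_offset: int = _DEFAULT_OFFSET
    fraction_indels: float = 0.1
    fraction_multiallelic: float = 0.05
    merged_rsid_count: int = 20
    n_samples: float = 50_000.0
    plan: CorruptionPlan = field(default_factory=CorruptionPlan)
    overlap_corruptions: bool = False


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def _simulate_panel_records(spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_variants
    chroms = np.sort(rng.choice(np.array(spec.chromosomes), size=n))
    rsids = np.sort(rng.choice(np.arange(10_000, 10_000_000), size=n, replace=False))
    pos_37 = np.zeros(n, dtype=np.int64)
    for c in spec.chromosomes:
        m = chroms == c
        pos_37[m] = np.sort(rng.choice(
            np.arange(10_000, 50_000_000), size=int(m.sum()), replace=False))
    pos_38 = pos_37 + spec.build_offset

    ref = rng.choice(_BASES, size=n).astype(object)  # object dtype: alleles can grow
    alt = np.array([rng.choice([b for b in _BASES if b != r]) for r in ref])
    alts = [[a] for a in alt]

    n_multi = int(round(spec.fraction_multiallelic * n))
    for i in rng.choice(n, size=n_multi, replace=False):
        extra = [b for b in _BASES if b != ref[i] and b not in alts[i]]
        alts[i] = sorted(alts[i] + [str(rng.choice(extra))])

    is_indel = np.zeros(n, dtype=bool)
    n_indel = int(round(spec.fraction_indels * n))
    for i in rng.choice(n, size=n_indel, replace=False):
        ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        if rng.random() < 0.5:
            alts[i] = [ref[i] + ins]          # insertion, already left-trimmed
        else:
            ref[i], alts[i] = ref[i] + ins, [ref[i]]  # deletion
        is_indel[i] = True

    return pd.DataFrame({
        "RSID": rsids.astype("int64"),
        "CHR": pd.array(chroms, dtype="string"),
        "POS_37": pos_37,
        "POS_38": pos_38,
        "REF": pd.array(ref, dtype="string"),
        "ALT": alts,
        "is_indel": is_indel,
    })


def make_reference(spec: FixtureSpec, out_dir: str | Path) -> ReferencePanel:
    """Write a curated synthetic panel (SNV + indel partitions, merged-rsID map)."""
    rng = np.random.default_rng(spec.seed)
    records = _simulate_panel_records(spec, rng)

    merged = pd.DataFrame({"OLD_RSID": pd.Series(dtype="int64"),
                           "NEW_RSID": pd.Series(dtype="int64")})
    if spec.merged_rsid_count > 0:
        targets = rng.choice(records["RSID"].to_numpy(),
                             size=spec.merged_rsid_count, replace=False)
        old = np.sort(rng.choice(np.arange(1, 10_000),
                                 size=spec.merged_rsid_count, replace=False))
        merged = pd.DataFrame({"OLD_RSID": old.astype("int64"),
                               "NEW_RSID": targets.astype("int64")})
        if spec.merged_rsid_count >= 2:
            # one two-hop chain to exercise transitive resolution
            merged.loc[merged.index[0], "NEW_RSID"] = int(merged["OLD_RSID"].iloc[1])

    snvs = records[~records["is_indel"]].drop(columns="is_indel")
    indels = records[records["is_indel"]].drop(columns="is_indel")
    return write_reference(snvs, out_dir, merged=merged, indels=indels)


def make_uncurated_reference(
    spec: FixtureSpec,
    n_multi_position: int = 5,
    n_duplicate_position: int = 4,
    n_chr_mismatch: int = 3,
    n_missing_build: int = 2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clean records plus planted curation violations, with expected filter counts.

    Each multi-position rsID contributes *two* records, both removed by filter
    1; each duplicate-position record is a fresh (larger) rsID at an existing
    site, removed by filter 2; and so on.  Returns (raw records in the
    :data:`gwaskit.reference.RAW_COLUMNS` layout, expected per-filter counts).
    """
    rng = np.random.default_rng(spec.seed + 101)
    base = _simulate_panel_records(spec, rng).drop(columns="is_indel")
    raw = pd.DataFrame({
        "RSID": base["RSID"], "CHR_37": base["CHR"], "POS_37": base["POS_37"],
        "CHR_38": base["CHR"], "POS_38": base["POS_38"],
        "REF": base["REF"], "ALT": base["ALT"],
    })
    extras = []
    next_rsid = int(base["RSID"].max()) + 1
    free_pos = 60_000_000  # beyond any simulated position -> guaranteed fresh sites

    for _ in range(n_multi_position):
        rsid, next_rsid = next_rsid, next_rsid + 1
        for _ in range(2):  # same rsID, two distinct positions
            extras.append(dict(RSID=rsid, CHR_37="1", POS_37=free_pos,
                               CHR_38="1", POS_38=free_pos + spec.build_offset,
                               REF="A", ALT=["G"]))
            free_pos += 1

    dup_sites = rng.choice(len(base), size=n_duplicate_position, replace=False)
    for i in dup_sites:
        rsid, next_rsid = next_rsid, next_rsid + 1  # larger than every base rsID
        r = base.iloc[int(i)]
        extras.append(dict(RSID=rsid, CHR_37=r["CHR"], POS_37=int(r["POS_37"]),
                           CHR_38=r["CHR"], POS_38=int(r["POS_38"]),
                           REF=str(r["REF"]), ALT=list(r["ALT"])))

    for _ in range(n_chr_mismatch):
        rsid, next_rsid = next_rsid, next_rsid + 1
        extras.append(dict(RSID=rsid, CHR_37="1", POS_37=free_pos,
                           CHR_38="2", POS_38=free_pos + spec.build_offset,
                           REF="C", ALT=["T"]))
        free_pos += 1

    for _ in range(n_missing_build):
        rsid, next_rsid = next_rsid, next_rsid + 1
        extras.append(dict(RSID=rsid, CHR_37="1", POS_37=free_pos,
                           CHR_38=pd.NA, POS_38=pd.NA, REF="G", ALT=["A"]))
        free_pos += 1

    out = pd.concat([raw, pd.DataFrame(extras)], ignore_index=True)
    out = out.sample(frac=1.0, random_state=spec.seed).reset_index(drop=True)
    expected = {
        "multi_position_rsid": 2 * n_multi_position,
        "duplicate_position": n_duplicate_position,
        "chromosome_mismatch": n_chr_mismatch,
        "missing_build_position": n_missing_build,
    }
    return out, expected


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _simulate_stats(n: int, n_samples: float, rng: np.random.Generator) -> pd.DataFrame:
    eaf = rng.uniform(0.05, 0.95, size=n)
    beta_true = rng.normal(0.0, 0.02, size=n)
    se0 = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_samples)
    z = beta_true / se0 + rng.normal(0.0, 1.0, size=n)
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * (n_samples + z**2))
    b = z * se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"EAF": eaf, "B": b, "SE": se, "Z": z, "P": p,
                         "N": float(n_samples)})


def _alias_headers(columns: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Pick a random published alias for each canonical column name."""
    out = {}
    for c in columns:
        cands = [c] + [a for a in _ALIASES.get(c, ()) if a not in ("id", "alt", "ref")]
        out[c] = str(rng.choice(cands))
    return out


@dataclass
class SumstatsFixture:
    """A messy raw file plus everything the pipeline is expected to produce."""

    raw_path: Path
    raw: pd.DataFrame                 # messy table exactly as written
    truth: pd.DataFrame               # expected harmonized output (canonical schema)
    expected_report: dict[str, int]   # expected per-filter removal counts
    build: str                        # generating build, "GRCh37"/"GRCh38"


def make_sumstats(
    spec: FixtureSpec,
    panel: ReferencePanel,
    build: int | str = 38,
    out_path: str | Path | None = None,
    id_mode: str = "chrpos_rsid",
    gz: bool = False,
    alias_headers: bool = True,
    use_merged_ids: int = 0,
) -> SumstatsFixture:
    """Draw sumstats from the panel at one build's coordinates; plant corruptions.

    ``id_mode`` selects the identity columns written: "chrpos_rsid" (all
    three; the pipeline drops and restores RSID), "chrpos", or "rsid".
    The returned ground truth is the expected *harmonized* table: corrupted
    rows destined for removal are excluded, surviving corruptions (compound
    ids, chr prefixes, swapped alleles) are reflected as the pipeline leaves
    them.
    """
    build = str(build)
    if build not in ("37", "38"):
        raise ValueError(f"unknown build {build!r}")
    plan = spec.plan
    rng = np.random.default_rng(spec.seed + 7)

    pool = panel.scan(kind="both").sort_values(["CHR", "POS_38"]).reset_index(drop=True)
    n = len(pool)
    statsim = _simulate_stats(n, spec.n_samples, rng)

    df = pd.DataFrame({
        "RSID": "rs" + pool["RSID"].astype(str),
        "CHR": pool["CHR"].astype(str),
        "POS": pool[f"POS_{build}"].astype("int64"),
        "EffectAllele": [str(a[0]) for a in pool["ALT"]],
        "OtherAllele": pool["REF"].astype(str),
    })
    df = pd.concat([df, statsim], axis=1)
    truth_extra = pd.DataFrame({
        "POS_37": pool["POS_37"].to_numpy(),
        "POS_38": pool["POS_38"].to_numpy(),
        "indel": (pool["REF"].str.len() > 1)
        | pd.Series([len(a[0]) > 1 for a in pool["ALT"]]),
        "rsid_num": pool["RSID"].to_numpy(),
        "n_alts": pd.Series([len(a) for a in pool["ALT"]]),
    })

    # second allele rows for multiallelic panel sites -> multi_allelic flags
    multi_idx = truth_extra.index[truth_extra["n_alts"] > 1]
    extra_rows = []
    for i in multi_idx:
        r = df.loc[i].copy()
        second = str(pool["ALT"].iloc[i][1])
        r["EffectAllele"] = second
        s2 = _simulate_stats(1, spec.n_samples, rng).iloc[0]
        for c in ("EAF", "B", "SE", "Z", "P", "N"):
            r[c] = s2[c]
        extra_rows.append((i, r))

    removed = np.zeros(len(df), dtype=bool)   # rows that will not survive
    used = np.zeros(len(df), dtype=bool)      # rows claimed by some corruption
    used[multi_idx] = True                    # keep multiallelic rows pristine

    is_indel_row = truth_extra["indel"].to_numpy()

    def claim(count: int, mask: np.ndarray | None = None) -> np.ndarray:
        free = ~used if not spec.overlap_corruptions else np.ones(len(df), bool)
        if mask is not None:
            free = free & mask
        candidates = np.flatnonzero(free)
        if count > len(candidates):
            raise ValueError("corruption plan exceeds available rows")
        idx = np.sort(rng.choice(candidates, size=count, replace=False))
        used[idx] = True
        return idx

    corruptions: dict[str, np.ndarray] = {
        "na_rows": claim(plan.na_rows),
        "invalid_p": claim(plan.invalid_p),
        "invalid_eaf": claim(plan.invalid_eaf),
        "invalid_se": claim(plan.invalid_se),
        # single-base replacement pairs exist only for SNV rows
        "allele_incompatible": claim(plan.allele_incompatible, mask=~is_indel_row),
        "off_panel": claim(plan.off_panel),
        "compound_ids": claim(plan.compound_ids),
        "chr_prefixed": claim(plan.chr_prefixed),
        "swapped_alleles": claim(plan.swapped_alleles),
        "duplicate_rows": claim(plan.duplicate_rows),
    }

    idx = corruptions["na_rows"]
    df.loc[idx, "EffectAllele"] = pd.NA
    removed[idx] = True
    idx = corruptions["invalid_p"]
    df.loc[idx, "P"] = rng.uniform(1.0001, 5.0, size=len(idx))
    removed[idx] = True
    idx = corruptions["invalid_eaf"]
    df.loc[idx, "EAF"] = rng.uniform(1.0001, 2.0, size=len(idx))
    removed[idx] = True
    idx = corruptions["invalid_se"]
    df.loc[idx, "SE"] = -np.abs(df.loc[idx, "SE"])
    removed[idx] = True
    idx = corruptions["off_panel"]
    if id_mode == "rsid":
        df.loc[idx, "RSID"] = [f"rs{99_000_000 + j}" for j in range(len(idx))]
    else:
        df.loc[idx, "POS"] = np.arange(90_000_000, 90_000_000 + len(idx))
    removed[idx] = True
    idx = corruptions["allele_incompatible"]
    for i in idx:
        ref_a, alt_a = str(df.at[i, "OtherAllele"]), str(df.at[i, "EffectAllele"])
        if complement(alt_a) == ref_a:  # palindromic ref/alt: use the other couple
            pair = sorted(set("ACGT") - {ref_a, alt_a})
        else:  # {alt, comp(alt)} excludes ref directly and under complement
            pair = [alt_a, complement(alt_a)]
        df.at[i, "EffectAllele"], df.at[i, "OtherAllele"] = pair[0], pair[1]
    removed[idx] = True

    idx = corruptions["compound_ids"]
    if len(idx) and id_mode != "rsid":
        raise ValueError("compound_ids corruption requires id_mode='rsid'")
    for i in idx:
        df.at[i, "RSID"] = f"{df.at[i, 'CHR']}:{df.at[i, 'POS']}:" \
                           f"{df.at[i, 'OtherAllele']}:{df.at[i, 'EffectAllele']}"
    chr_prefix_idx = corruptions["chr_prefixed"]
    if len(chr_prefix_idx) and id_mode == "rsid":
        raise ValueError("chr_prefixed corruption requires a CHR column")

    if use_merged_ids:
        # rewrite some rsIDs to retired ids; harmonization must restore them
        if id_mode != "rsid":
            raise ValueError("use_merged_ids requires id_mode='rsid'")
        merged = panel.merged
        if len(merged) < use_merged_ids:
            raise ValueError("panel has too few merged rsIDs")
        new_to_old = dict(zip(merged["NEW_RSID"].astype(int),
                              merged["OLD_RSID"].astype(int)))
        targets = [i for i in np.flatnonzero(~used)
                   if int(truth_extra.at[i, "rsid_num"]) in new_to_old]
        if len(targets) < use_merged_ids:
            raise ValueError("too few unclaimed rows hit the merged map")
        for i in targets[:use_merged_ids]:
            used[i] = True
            df.at[i, "RSID"] = f"rs{new_to_old[int(truth_extra.at[i, 'rsid_num'])]}"

    idx = corruptions["swapped_alleles"]
    ea = df.loc[idx, "EffectAllele"].copy()
    df.loc[idx, "EffectAllele"] = df.loc[idx, "OtherAllele"].to_numpy()
    df.loc[idx, "OtherAllele"] = ea.to_numpy()
    df.loc[idx, "B"] = -df.loc[idx, "B"]
    df.loc[idx, "Z"] = -df.loc[idx, "Z"]
    df.loc[idx, "EAF"] = 1.0 - df.loc[idx, "EAF"]

    # ground truth BEFORE appending duplicates / dropping id columns
    keep = ~removed
    truth = pd.DataFrame({
        "RSID": "rs" + truth_extra.loc[keep, "rsid_num"].astype(str),
        "CHR": df.loc[keep, "CHR"].astype(str),
        "POS_37": truth_extra.loc[keep, "POS_37"].to_numpy(),
        "POS_38": truth_extra.loc[keep, "POS_38"].to_numpy(),
        "EffectAllele": df.loc[keep, "EffectAllele"].to_numpy(),
        "OtherAllele": df.loc[keep, "OtherAllele"].to_numpy(),
        "EAF": df.loc[keep, "EAF"].to_numpy(),
        "B": df.loc[keep, "B"].to_numpy(),
        "SE": df.loc[keep, "SE"].to_numpy(),
        "Z": df.loc[keep, "Z"].to_numpy(),
        "P": df.loc[keep, "P"].to_numpy(),
        "N": df.loc[keep, "N"].to_numpy(),
        "indel": truth_extra.loc[keep, "indel"].to_numpy(),
        "multi_allelic": np.zeros(int(keep.sum()), dtype=bool),
        "strand_flipped": np.zeros(int(keep.sum()), dtype=bool),
    })
    if extra_rows:
        add = []
        for i, r in extra_rows:
            add.append({
                "RSID": f"rs{truth_extra.at[i, 'rsid_num']}", "CHR": r["CHR"],
                "POS_37": truth_extra.at[i, "POS_37"],
                "POS_38": truth_extra.at[i, "POS_38"],
                "EffectAllele": r["EffectAllele"], "OtherAllele": r["OtherAllele"],
                "EAF": r["EAF"], "B": r["B"], "SE": r["SE"], "Z": r["Z"],
                "P": r["P"], "N": r["N"],
                "indel": bool(truth_extra.at[i, "indel"]),
                "multi_allelic": True, "strand_flipped": False,
            })
        truth.loc[truth["RSID"].isin({a["RSID"] for a in add}), "multi_allelic"] = True
        truth = pd.concat([truth, pd.DataFrame(add)], ignore_index=True)
    truth = truth.sort_values(["CHR", "POS_38", "EffectAllele"]).reset_index(drop=True)

    # assemble the messy file
    messy = df.copy()
    if extra_rows:
        messy = pd.concat([messy, pd.DataFrame([r for _, r in extra_rows])],
                          ignore_index=True)
    dup_idx = corruptions["duplicate_rows"]
    if len(dup_idx):
        messy = pd.concat([messy, df.loc[dup_idx]], ignore_index=True)
    if len(chr_prefix_idx):
        messy.loc[chr_prefix_idx, "CHR"] = "chr" + messy.loc[chr_prefix_idx, "CHR"].astype(str)

    if id_mode == "chrpos":
        messy = messy.drop(columns=["RSID"])
    elif id_mode == "rsid":
        messy = messy.drop(columns=["CHR", "POS"])
    elif id_mode != "chrpos_rsid":
        raise ValueError(f"unknown id_mode {id_mode!r}")

    messy = messy.sample(frac=1.0, random_state=spec.seed + 13).reset_index(drop=True)
    header_map = _alias_headers(list(messy.columns), rng) if alias_headers \
        else {c: c for c in messy.columns}
    written = messy.rename(columns=header_map)

    if out_path is None:
        out_path = Path(f"sumstats_seed{spec.seed}.tsv" + (".gz" if gz else ""))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    csv = written.to_csv(sep="\t", index=False, na_rep="NA", float_format="%.17g")
    if gz:
        with open(out_path, "wb") as raw_fh, \
                gzip.GzipFile(fileobj=raw_fh, mode="wb", mtime=0) as fh:
            fh.write(csv.encode())
    else:
        out_path.write_text(csv)

    return SumstatsFixture(
        raw_path=out_path, raw=written, truth=truth,
        expected_report=plan.expected_report(),
        build="GRCh37" if build == "37" else "GRCh38",
    )


def complement(a) -> str:
    from ._util import complement_allele

    return complement_allele(str(a)) if pd.notna(a) else ""


def make_frequency_reference(
    spec: FixtureSpec, panel: ReferencePanel, out_path: str | Path,
    n_discrepant: int = 0,
) -> Path:
    """Per-population alternate-allele frequencies for every panel variant.

    Frequencies are small jitters of a common latent frequency; when
    ``n_discrepant`` > 0 that many variants get EUR frequencies displaced by
    more than the 0.2 flag threshold.
    """
    rng = np.random.default_rng(spec.seed + 23)
    pool = panel.scan(kind="both")
    n = len(pool)
    latent = rng.uniform(0.05, 0.95, size=n)
    out = pd.DataFrame({"RSID": pool["RSID"].astype("int64"),
                        "ALT": [str(a[0]) for a in pool["ALT"]]})
    for pop in ("AFR", "AMR", "EAS", "EUR", "SAS"):
        out[pop] = np.clip(latent + rng.normal(0, 0.01, size=n), 0.001, 0.999)
    if n_discrepant:
        idx = rng.choice(n, size=n_discrepant, replace=False)
        out.loc[idx, "EUR"] = np.clip(1.0 - out.loc[idx, "EUR"], 0.001, 0.999)
    import pyarrow as pa
    import pyarrow.parquet as pq

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pq.write_table(pa.Table.from_pandas(out, preserve_index=False), out_path)
    return out_path
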