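"""End-to-end harmonization: parse → map → clean → repair identity → repair stats → write.

``harmonize`` is the single entry point binding the stage modules in their
fixed order.  Stages never silently reorder: removal accounting in the
:class:`~gwaskit.cleaning.CleaningReport` is only meaningful for one ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import cleaning, identity_repair, ingest, stats_repair, storage
from .cleaning import CleaningReport
from .identity_repair import BuildCall
from .reference import ReferencePanel, load_reference
from .storage import CleanedDataset

logger = logging.getLogger(__name__)


@dataclass
class HarmonizeResult:
    """Everything one harmonization run produced."""

    table: pd.DataFrame
    report: CleaningReport
    build: BuildCall | None
    dataset: CleanedDataset | None = None


def harmonize(
    source,
    panel: ReferencePanel | str | Path,
    column_map: Mapping[str, str] | None = None,
    indel_strategy: str = "qc",
    freq_ref=None,
    population: str | None = None,
    flag_freq_diff: bool = True,
    output: str | Path | None = None,
    output_format: str = "hivestyle",
    overwrite: bool = False,
) -> HarmonizeResult:
    """Validate, repair and harmonize one summary-statistics table.

    Parameters
    ----------
    source
        File path (TSV/CSV/semicolon/whitespace, optionally gzipped) or an
        in-memory :class:`pandas.DataFrame`.
    panel
        A loaded :class:`~gwaskit.reference.ReferencePanel` or its directory.
    column_map
        Optional explicit original-to-canonical header mapping; overrides
        guessing for the named headers.
    indel_strategy
        "qc" (match indels against the indel reference partition), "keep"
        (pass them through unmatched) or "drop".
    freq_ref, population, flag_freq_diff
        Optional per-population frequency reference (DataFrame or Parquet
        path), the population label, and whether to flag |EAF-EAF_ref| > 0.2.
    output, output_format, overwrite
        When ``output`` is given the harmonized table is written there as a
        :class:`~gwaskit.storage.CleanedDataset`.
    """
    if not isinstance(panel, ReferencePanel):
        panel = load_reference(panel)

    raw = ingest.parse_input(source)
    mapping = ingest.guess_names(raw.headers, overrides=column_map)
    raw = ingest.select_correct_columns(raw, mapping)

    report = CleaningReport(input_rows=raw.n_rows)
    df = raw.df
    df = cleaning.remove_rows_with_na(df, report)
    df = cleaning.remove_duplicates(df, report)
    df = cleaning.detect_indels(df, indel_strategy, report)
    df = cleaning.validate_columns(df, report)

    df = identity_repair.split_compound_ids(df)

    kept_indels = None
    if indel_strategy == "keep" and df["indel"].fillna(False).any():
        mask = df["indel"].fillna(False).astype(bool)
        kept_indels, df = df[mask], df[~mask]

    has_chrpos = {"CHR", "POS"} <= set(df.columns) and \
        (df["CHR"].notna() & df["POS"].notna()).any()
    build = identity_repair.infer_build(df, panel) if has_chrpos else None
    if build is not None:
        logger.info("genome build: %s (%d/%d vs %d/%d matches)", build.build,
                    build.matches_37, build.n_sampled, build.matches_38, build.n_sampled)

    df = identity_repair.repair_ids(df, panel, build, report)
    df = identity_repair.flag_multiallelic(df)
    df = stats_repair.repair_stats(df)

    if freq_ref is not None:
        if isinstance(freq_ref, (str, Path)):
            freq_ref = stats_repair.load_frequency_reference(freq_ref)
        if population is None:
            raise stats_repair.StatsError("a population label is required with freq_ref")
        df = stats_repair.append_reference_freq(df, freq_ref, population)
        if flag_freq_diff:
            df = stats_repair.add_freq_diff_flag(df)

    if kept_indels is not None:
        df = pd.concat([df, kept_indels], ignore_index=True)

    df = storage.canonicalize(df)
    df = df.sort_values(
        ["CHR", "POS_38", "EffectAllele", "OtherAllele"], na_position="last"
    ).reset_index(drop=True)

    dataset = None
    if output is not None:
        metadata = {
            "source": str(getattr(raw, "source", source)),
            "build_call": build.to_dict() if build else None,
            "rows": int(len(df)),
        }
        dataset = storage.write_output(
            df, output, output_format=output_format, overwrite=overwrite,
            report=report, metadata=metadata)
    return HarmonizeResult(table=df, report=report, build=build, dataset=dataset)
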