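"""Build inference, compound-id splitting, reference merging, multiallelic flags."""

import dataclasses
import re

import numpy as np
import pandas as pd
import pytest

from gwaskit.cleaning import CleaningReport
from gwaskit.fixtures import FixtureSpec, make_sumstats
from gwaskit.identity_repair import (
    BuildCall,
    IdentityError,
    flag_multiallelic,
    infer_build,
    repair_ids,
    split_compound_ids,
)
from gwaskit.pipeline import harmonize


class TestInferBuild:
    def test_recovers_generating_build(self, panel_clean):
        ref = panel_clean.scan(kind="snv").head(200)
        for build in ("37", "38"):
            tbl = pd.DataFrame({"CHR": ref["CHR"].astype(str),
                                "POS": ref[f"POS_{build}"]})
            call = infer_build(tbl, panel_clean)
            assert call.build == f"GRCh{build}"
            assert call.n_sampled == 200

    def test_counts_match_exhaustive_oracle(self, panel_clean):
        ref = panel_clean.scan(kind="snv")
        rng = np.random.default_rng(3)
        pos = np.concatenate([ref["POS_38"].to_numpy()[:50],
                              rng.integers(70_000_000, 80_000_000, size=50)])
        tbl = pd.DataFrame({"CHR": ref["CHR"].astype(str).tolist()[:50] + ["1"] * 50,
                            "POS": pos})
        call = infer_build(tbl, panel_clean)
        # oracle: exhaustive membership test per build
        for build, got in (("37", call.matches_37), ("38", call.matches_38)):
            want = 0
            for chrom in set(tbl["CHR"]):
                sub = tbl.loc[tbl["CHR"] == chrom, "POS"]
                allpos = set(panel_clean.scan(chrom, kind="both")[f"POS_{build}"])
                want += int(sub.isin(allpos).sum())
            assert got == want
        assert call.build == ("GRCh37" if call.matches_37 > call.matches_38
                              else "GRCh38")

    def test_sample_bounded_by_table_size(self, panel_clean):
        ref = panel_clean.scan(kind="snv").head(17)
        tbl = pd.DataFrame({"CHR": ref["CHR"].astype(str), "POS": ref["POS_38"]})
        assert infer_build(tbl, panel_clean).n_sampled == 17

    def test_tie_breaks_to_grch38_with_warning(self, panel_clean):
        ref = panel_clean.scan("1", kind="snv")
        # one row matching only build 37, one matching only build 38
        tbl = pd.DataFrame({"CHR": ["1", "1"],
                            "POS": [int(ref["POS_37"].iloc[0]),
                                    int(ref["POS_38"].iloc[1])]})
        with pytest.warns(UserWarning, match="tie"):
            call = infer_build(tbl, panel_clean)
        assert call.build == "GRCh38"
        assert call.matches_37 == call.matches_38 == 1

    def test_zero_overlap_is_fatal(self, panel_clean):
        tbl = pd.DataFrame({"CHR": ["1"], "POS": [99_999_999]})
        with pytest.raises(IdentityError, match="no overlap"):
            infer_build(tbl, panel_clean)


class TestSplitCompoundIds:
    def test_patterns(self):
        df = pd.DataFrame({"RSID": pd.array(
            ["1:12345:A:G", "rs789", "chr2:555", "CH2:7:a:t", "MT:33"],
            dtype="string")})
        out = split_compound_ids(df)
        assert out["CHR"].fillna("-").tolist() == ["1", "-", "2", "2", "MT"]
        assert out["POS"].fillna(-1).tolist() == [12345, -1, 555, 7, 33]
        assert out["RSID"].isna().tolist() == [True, False, True, True, True]

    def test_matches_regex_oracle_on_random_strings(self):
        oracle = re.compile(
            r"^(?:chr|ch)?(\d{1,2}|x|y|mt|m)[:_](\d+)([:_][acgt]+[:_][acgt]+)?$",
            re.IGNORECASE)
        rng = np.random.default_rng(5)
        pieces = ["rs12", "1:100", "chr1:100", "1:100:A:G", "q:5", "X:9",
                  "25:10", "1:100:AT:G", "::", "1:", "ch3:44_a_g", "3_44"]
        for _ in range(200):
            s = pieces[int(rng.integers(len(pieces)))]
            df = pd.DataFrame({"RSID": pd.array([s], dtype="string")})
            out = split_compound_ids(df)
            assert out["RSID"].isna().iloc[0] == bool(oracle.match(s))


class TestRepairIds:
    def _tbl_from_panel(self, panel, build="38", n=50):
        ref = panel.scan(kind="snv").head(n)
        return pd.DataFrame({
            "CHR": ref["CHR"].astype("string"),
            "POS": ref[f"POS_{build}"].astype("Int64"),
            "EffectAllele": pd.array([a[0] for a in ref["ALT"]], dtype="string"),
            "OtherAllele": ref["REF"].astype("string"),
        }), ref

    def test_position_path_restores_rsid_and_both_builds(self, panel_clean):
        tbl, ref = self._tbl_from_panel(panel_clean)
        call = infer_build(tbl, panel_clean)
        rep = CleaningReport(input_rows=len(tbl))
        out = repair_ids(tbl, panel_clean, call, rep)
        assert len(out) == len(tbl)
        assert sorted(out["RSID"]) == sorted("rs" + ref["RSID"].astype(str))
        assert out[["POS_37", "POS_38"]].notna().all().all()
        assert rep.removed["no_dbsnp_match"] == 0

    def test_off_panel_and_incompatible_rows_counted(self, panel_clean):
        tbl, ref = self._tbl_from_panel(panel_clean, n=10)
        tbl.loc[0, "POS"] = 99_000_000          # no panel entry
        tbl.loc[1, "EffectAllele"] = "AAAA"     # allele clash (still matches pos)
        tbl.loc[1, "OtherAllele"] = "TTTT"
        call = BuildCall("GRCh38", 10, 0, 10)
        rep = CleaningReport(input_rows=len(tbl))
        out = repair_ids(tbl, panel_clean, call, rep)
        assert rep.removed["no_dbsnp_match"] == 1
        assert rep.removed["allele_incompatible"] == 1
        assert len(out) == 8

    def test_strand_flipped_pair_matches_and_is_flagged(self, panel_clean):
        tbl, ref = self._tbl_from_panel(panel_clean, n=200)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        # complement a non-palindromic SNV pair
        snv = (tbl["EffectAllele"].str.len() == 1) & (tbl["OtherAllele"].str.len() == 1)
        pal = tbl["EffectAllele"].map(comp) == tbl["OtherAllele"]
        i = tbl.index[snv & ~pal][0]
        tbl.loc[i, "EffectAllele"] = comp[tbl.loc[i, "EffectAllele"]]
        tbl.loc[i, "OtherAllele"] = comp[tbl.loc[i, "OtherAllele"]]
        call = infer_build(tbl, panel_clean)
        out = repair_ids(tbl, panel_clean, call, CleaningReport(input_rows=len(tbl)))
        flipped = out.loc[out["RSID"] == "rs" + str(ref.loc[i, "RSID"]),
                          "strand_flipped"]
        assert len(out) == len(tbl)
        assert flipped.tolist() == [True]
        assert out["strand_flipped"].sum() == 1

    def test_rsid_path_attaches_positions_and_merged_ids(self, panel_clean):
        ref = panel_clean.scan(kind="snv").head(30)
        merged = panel_clean.merged
        old_of = dict(zip(merged["NEW_RSID"], merged["OLD_RSID"]))
        rsids = ["rs" + str(old_of.get(r, r)) for r in ref["RSID"]]
        n_retired = sum(int(r in old_of) for r in ref["RSID"])
        tbl = pd.DataFrame({
            "RSID": pd.array(rsids, dtype="string"),
            "EffectAllele": pd.array([a[0] for a in ref["ALT"]], dtype="string"),
            "OtherAllele": ref["REF"].astype("string"),
        })
        rep = CleaningReport(input_rows=len(tbl))
        out = repair_ids(tbl, panel_clean, None, rep)
        assert len(out) == len(tbl)
        # retired ids were updated to the current ones before matching
        assert sorted(out["RSID"]) == sorted("rs" + ref["RSID"].astype(str))
        assert out[["CHR", "POS_37", "POS_38"]].notna().all().all()
        assert n_retired > 0  # the fixture really exercised the merged map

    def test_dual_path_equivalence(self, panel_clean, tmp_path):
        """Matching by CHR:POS vs by rsID yields identical surviving variants."""
        spec = FixtureSpec(seed=21, n_variants=250, merged_rsid_count=0)
        from gwaskit.fixtures import make_reference

        panel = make_reference(spec, tmp_path / "panel")
        by_pos = make_sumstats(spec, panel, build=38,
                               out_path=tmp_path / "pos.tsv", id_mode="chrpos")
        by_rsid = make_sumstats(spec, panel, build=38,
                                out_path=tmp_path / "rsid.tsv", id_mode="rsid")
        a = harmonize(by_pos.raw_path, panel).table
        b = harmonize(by_rsid.raw_path, panel).table
        key = ["RSID", "CHR", "POS_37", "POS_38", "EffectAllele", "OtherAllele"]
        assert a[key].to_records(index=False).tolist() == \
            b[key].to_records(index=False).tolist()


class TestFlagMultiallelic:
    def test_shared_rsid_flagged_on_all_rows(self):
        df = pd.DataFrame({"RSID": ["rs10", "rs10", "rs11"]})
        out = flag_multiallelic(df)
        assert out["multi_allelic"].tolist() == [True, True, False]

    def test_empty_table(self):
        out = flag_multiallelic(pd.DataFrame({"RSID": []}))
        assert len(out) == 0 and "multi_allelic" in out.columns

    def test_surviving_rows_fully_identified(self, harmonized_clean):
        t = harmonized_clean.table
        assert t[["RSID", "CHR", "POS_37", "POS_38"]].notna().all().all()
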