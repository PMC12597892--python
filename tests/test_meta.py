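"""Inverse-variance pooling, heterogeneity statistics, allele alignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gwaskit.meta import MetaError, align_effects, meta_analyse, to_metal_tsv
from gwaskit.storage import write_output


def _study_frame(rsids, b, se, ea="A", oa="G", chrom="1", n=1000.0):
    k = len(rsids)
    pos = [1000 + 10 * i for i in range(k)]
    return pd.DataFrame({
        "RSID": rsids, "CHR": [chrom] * k, "POS_37": pos, "POS_38": pos,
        "EffectAllele": [ea] * k if isinstance(ea, str) else ea,
        "OtherAllele": [oa] * k if isinstance(oa, str) else oa,
        "B": b, "SE": se, "N": [n] * k,
    })


def _datasets(tmp_path, frames):
    return [write_output(f, tmp_path / f"s{i}") for i, f in enumerate(frames)]


class TestPooling:
    def test_two_studies_closed_form(self, tmp_path):
        # w = 100 each: B_meta = 0.2, SE = 1/sqrt(200), Q = 100*(0.01+0.01) = 2
        ds = _datasets(tmp_path, [_study_frame(["rs1"], [0.1], [0.1]),
                                  _study_frame(["rs1"], [0.3], [0.1])])
        r = meta_analyse(ds, min_k=2)
        assert r["B_meta"].iloc[0] == pytest.approx(0.2, rel=1e-12)
        assert r["SE_meta"].iloc[0] == pytest.approx(1 / np.sqrt(200), rel=1e-12)
        assert r["Q"].iloc[0] == pytest.approx(2.0, rel=1e-12)
        assert r["I2"].iloc[0] == pytest.approx(50.0, rel=1e-12)
        assert r["P_het"].iloc[0] == pytest.approx(sps.chi2.sf(2.0, 1), rel=1e-12)
        assert r["direction"].iloc[0] == "++"
        assert r["N_total"].iloc[0] == 2000.0

    def test_three_equal_studies_symmetry(self, tmp_path):
        ds = _datasets(tmp_path, [_study_frame(["rs1"], [0.2], [0.05])] * 3)
        r = meta_analyse(ds, min_k=2)
        assert r["B_meta"].iloc[0] == pytest.approx(0.2, rel=1e-12)
        assert r["SE_meta"].iloc[0] == pytest.approx(0.05 / np.sqrt(3), rel=1e-12)
        assert r["Q"].iloc[0] == pytest.approx(0.0, abs=1e-18)
        assert r["I2"].iloc[0] == 0.0

    def test_single_study_variant_identity_when_min_k_1(self, tmp_path):
        ds = _datasets(tmp_path, [_study_frame(["rs1", "rs2"], [0.1, 0.2], [0.1, 0.1]),
                                  _study_frame(["rs1"], [0.1], [0.1])])
        r = meta_analyse(ds, min_k=1).set_index("RSID")
        assert r.loc["rs2", "B_meta"] == pytest.approx(0.2)
        assert r.loc["rs2", "SE_meta"] == pytest.approx(0.1)
        assert np.isnan(r.loc["rs2", "Q"]) and np.isnan(r.loc["rs2", "I2"])
        # and rs2 is omitted entirely at the default min_k
        assert "rs2" not in meta_analyse(ds, min_k=2)["RSID"].tolist()

    def test_fewer_than_two_datasets_fatal(self, tmp_path):
        ds = _datasets(tmp_path, [_study_frame(["rs1"], [0.1], [0.1])])
        with pytest.raises(MetaError, match="at least 2"):
            meta_analyse(ds)

    def test_schema_mismatch_names_dataset(self, tmp_path):
        good = write_output(_study_frame(["rs1"], [0.1], [0.1]), tmp_path / "good")
        bad_dir = tmp_path / "bad"
        bad = write_output(_study_frame(["rs1"], [0.1], [0.1]),
                           bad_dir, output_format="tsv")
        with pytest.raises(MetaError, match="bad"):
            meta_analyse([good, bad])


class TestAlignment:
    def test_swapped_alleles_contribute_negated_effect(self, tmp_path):
        ds = _datasets(tmp_path, [
            _study_frame(["rs1"], [0.1], [0.1], ea="A", oa="G"),
            _study_frame(["rs1"], [-0.1], [0.1], ea="G", oa="A"),
        ])
        r = meta_analyse(ds, min_k=2)
        assert r["B_meta"].iloc[0] == pytest.approx(0.1, rel=1e-12)
        assert r["Q"].iloc[0] == pytest.approx(0.0, abs=1e-18)
        assert r["direction"].iloc[0] == "++"

    def test_mismatched_allele_set_excluded_with_question_mark(self, tmp_path):
        ds = _datasets(tmp_path, [
            _study_frame(["rs1"], [0.1], [0.1], ea="A", oa="G"),
            _study_frame(["rs1"], [0.5], [0.1], ea="A", oa="C"),
            _study_frame(["rs1"], [0.1], [0.1], ea="A", oa="G"),
        ])
        r = meta_analyse(ds, min_k=2)
        assert r["k"].iloc[0] == 2
        assert r["direction"].iloc[0] == "+?+"
        assert r["B_meta"].iloc[0] == pytest.approx(0.1, rel=1e-12)

    def test_align_effects_involution(self):
        rows = pd.DataFrame({
            "RSID": ["rs1"] * 2, "_study": [0, 1],
            "EffectAllele": ["A", "G"], "OtherAllele": ["G", "A"],
            "B": [0.4, -0.4], "SE": [0.1, 0.1], "N": [10.0, 10.0]})
        eff, direction = align_effects(rows)
        assert [e.B for e in eff] == [0.4, 0.4]
        assert direction == ["+", "+"]

    def test_permutation_changes_direction_order_only(self, tmp_path):
        frames = [
            _study_frame(["rs1"], [0.1], [0.1]),
            _study_frame(["rs1"], [-0.2], [0.2]),
            _study_frame(["rs1"], [0.3], [0.15]),
        ]
        a = meta_analyse(_datasets(tmp_path / "a", frames), min_k=2)
        b = meta_analyse(_datasets(tmp_path / "b", frames[::-1]), min_k=2)
        for col in ("B_meta", "SE_meta", "Q", "I2", "P_meta"):
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0], rel=1e-12)
        assert a["direction"].iloc[0] == b["direction"].iloc[0][::-1]


class TestOracleAndCalibration:
    def _loop_oracle(self, b_mat, se_mat):
        """Explicit per-variant loops over studies."""
        out = []
        for b_row, se_row in zip(b_mat, se_mat):
            w = 1.0 / se_row**2
            bm = float((w * b_row).sum() / w.sum())
            sem = float(1.0 / np.sqrt(w.sum()))
            q = float((w * (b_row - bm) ** 2).sum())
            k = len(b_row)
            out.append((bm, sem, bm / sem, 2 * sps.norm.sf(abs(bm / sem)), q,
                        max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0))
        return np.array(out)

    def test_pooled_fields_match_loop_oracle(self, tmp_path):
        rng = np.random.default_rng(17)
        n_var, n_stud = 1000, 10
        rsids = [f"rs{i}" for i in range(n_var)]
        se = rng.uniform(0.02, 0.2, size=(n_var, n_stud))
        b = rng.normal(0, 0.05, size=(n_var, n_stud))
        ds = _datasets(tmp_path, [
            _study_frame(rsids, b[:, j], se[:, j]) for j in range(n_stud)])
        r = meta_analyse(ds, min_k=2).set_index("RSID").loc[rsids]
        oracle = self._loop_oracle(b, se)
        got = r[["B_meta", "SE_meta", "Z_meta", "P_meta", "Q", "I2"]].to_numpy()
        np.testing.assert_allclose(got, oracle, rtol=1e-10, atol=1e-12)

    def test_associativity_of_precision_weighted_pooling(self, tmp_path):
        rng = np.random.default_rng(23)
        frames = [_study_frame(["rs1"], [float(rng.normal())],
                               [float(rng.uniform(0.05, 0.2))]) for _ in range(3)]
        all3 = meta_analyse(_datasets(tmp_path / "all", frames), min_k=2)
        pair = meta_analyse(_datasets(tmp_path / "p", frames[:2]), min_k=2)
        merged = _study_frame(["rs1"], [float(pair["B_meta"].iloc[0])],
                              [float(pair["SE_meta"].iloc[0])])
        two = meta_analyse(_datasets(tmp_path / "m", [merged, frames[2]]), min_k=2)
        assert two["B_meta"].iloc[0] == pytest.approx(all3["B_meta"].iloc[0],
                                                      rel=1e-10)
        assert two["SE_meta"].iloc[0] == pytest.approx(all3["SE_meta"].iloc[0],
                                                       rel=1e-10)

    def test_pooled_error_calibration(self, tmp_path):
        """(B_meta - beta)/SE_meta should be standard normal across variants."""
        rng = np.random.default_rng(29)
        n_var, n_stud = 10_000, 10
        beta = rng.normal(0, 0.01, size=n_var)
        se = rng.uniform(0.02, 0.1, size=(n_var, n_stud))
        b = beta[:, None] + rng.normal(0, 1, size=(n_var, n_stud)) * se
        rsids = [f"rs{i}" for i in range(n_var)]
        ds = _datasets(tmp_path, [
            _study_frame(rsids, b[:, j], se[:, j]) for j in range(n_stud)])
        r = meta_analyse(ds, min_k=2).set_index("RSID").loc[rsids]
        z = (r["B_meta"].to_numpy() - beta) / r["SE_meta"].to_numpy()
        assert abs(z.mean()) < 0.05
        assert abs(z.var() - 1.0) < 0.05

    def test_se_meta_never_exceeds_best_study(self, tmp_path):
        rng = np.random.default_rng(31)
        se = rng.uniform(0.02, 0.3, size=(50, 4))
        b = rng.normal(size=(50, 4))
        rsids = [f"rs{i}" for i in range(50)]
        ds = _datasets(tmp_path, [
            _study_frame(rsids, b[:, j], se[:, j]) for j in range(4)])
        r = meta_analyse(ds, min_k=2).set_index("RSID").loc[rsids]
        assert (r["SE_meta"].to_numpy() <= se.min(axis=1) + 1e-15).all()


def test_metal_style_output(tmp_path):
    ds = _datasets(tmp_path, [_study_frame(["rs1"], [0.1], [0.1]),
                              _study_frame(["rs1"], [0.3], [0.1])])
    r = meta_analyse(ds, min_k=2)
    out = tmp_path / "metal.tsv"
    to_metal_tsv(r, out)
    back = pd.read_csv(out, sep="\t")
    assert list(back.columns) == ["MarkerName", "Allele1", "Allele2", "Effect",
                                  "StdErr", "P-value", "Direction", "HetISq",
                                  "HetChiSq", "HetDf", "HetPVal"]
    assert back["Effect"].iloc[0] == pytest.approx(0.2)
    assert back["HetDf"].iloc[0] == 1
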