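import dataclasses

import pytest

from gwaskit.fixtures import CorruptionPlan, FixtureSpec, make_reference, make_sumstats

CLEAN_SPEC = FixtureSpec(seed=1, n_variants=300)
CORRUPT_PLAN = CorruptionPlan(
    na_rows=5, duplicate_rows=7, invalid_p=3, invalid_eaf=2, invalid_se=2,
    off_panel=4, allele_incompatible=2, chr_prefixed=6, swapped_alleles=5,
)
CORRUPT_SPEC = dataclasses.replace(CLEAN_SPEC, seed=2, n_variants=400,
                                   plan=CORRUPT_PLAN)


@pytest.fixture(scope="session")
def panel_clean(tmp_path_factory):
    return make_reference(CLEAN_SPEC, tmp_path_factory.mktemp("panel_clean"))


@pytest.fixture(scope="session")
def fx_clean(panel_clean, tmp_path_factory):
    out = tmp_path_factory.mktemp("ss_clean") / "sumstats.tsv"
    return make_sumstats(CLEAN_SPEC, panel_clean, build=38, out_path=out)


@pytest.fixture(scope="session")
def panel_corrupt(tmp_path_factory):
    return make_reference(CORRUPT_SPEC, tmp_path_factory.mktemp("panel_corrupt"))


@pytest.fixture(scope="session")
def fx_corrupt(panel_corrupt, tmp_path_factory):
    out = tmp_path_factory.mktemp("ss_corrupt") / "sumstats.tsv.gz"
    return make_sumstats(CORRUPT_SPEC, panel_corrupt, build=37, out_path=out, gz=True)


@pytest.fixture(scope="session")
def harmonized_clean(fx_clean, panel_clean, tmp_path_factory):
    from gwaskit import harmonize

    out = tmp_path_factory.mktemp("ds_clean") / "ds"
    return harmonize(fx_clean.raw_path, panel_clean, output=out)
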