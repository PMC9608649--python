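import warnings

import pytest

import mutclust as mc
from mutclust.data import fixture_path, load_gene_config


@pytest.fixture(scope="session")
def ck2a_config():
    return load_gene_config("csnk2a1")


@pytest.fixture(scope="session")
def ck2b_config():
    return load_gene_config("csnk2b")


@pytest.fixture(scope="session")
def ck2a_records(ck2a_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mc.load_variant_table(fixture_path("csnk2a1_variants.tsv"), ck2a_config)


@pytest.fixture(scope="session")
def ck2b_records(ck2b_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mc.load_variant_table(fixture_path("csnk2b_variants.tsv"), ck2b_config)


@pytest.fixture(scope="session")
def ck2a_profile(ck2a_records, ck2a_config):
    profile, _ = mc.residue_patient_counts(ck2a_records, ck2a_config["protein_length"])
    return profile


@pytest.fixture(scope="session")
def ck2b_profile(ck2b_records, ck2b_config):
    profile, _ = mc.residue_patient_counts(ck2b_records, ck2b_config["protein_length"])
    return profile


@pytest.fixture(scope="session")
def ck2a_domains(ck2a_config):
    return mc.load_domain_config(
        fixture_path("csnk2a1_domains.json"), ck2a_config["protein_length"]
    )


@pytest.fixture(scope="session")
def ck2b_domains(ck2b_config):
    return mc.load_domain_config(
        fixture_path("csnk2b_domains.json"), ck2b_config["protein_length"]
    )
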