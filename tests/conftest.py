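import pandas as pd
import pytest

from ctcpanel.qpcr import CT_COLUMNS, validate_ct_table


def make_ct_table(rows):
    """rows: (patient, visit, fraction, gene, ct-or-None)."""
    return validate_ct_table(pd.DataFrame(rows, columns=CT_COLUMNS))


@pytest.fixture
def single_sample_table():
    """One patient/visit with reference in both fractions and a few targets."""
    return make_ct_table([
        ("P1", "V1", "CTC_ENRICHED", "B2M", 20.0),
        ("P1", "V1", "PBMC", "B2M", 21.0),
        ("P1", "V1", "CTC_ENRICHED", "CDH1", 25.0),
        ("P1", "V1", "PBMC", "CDH1", 28.0),
        ("P1", "V1", "CTC_ENRICHED", "VIM", 24.0),
        ("P1", "V1", "PBMC", "VIM", 25.0),
        ("P1", "V1", "CTC_ENRICHED", "KRT19", 30.0),
        ("P1", "V1", "PBMC", "KRT19", None),
        ("P1", "V1", "CTC_ENRICHED", "SNAI1", None),
        ("P1", "V1", "PBMC", "SNAI1", 28.0),
    ])


@pytest.fixture(scope="session")
def paper_like_cohort():
    from ctcpanel.simulate import generate_cohort, get_preset

    return generate_cohort(get_preset("paper-like").replace(seed=11))


@pytest.fixture(scope="session")
def table1_files():
    from ctcpanel.simulate import table1_cohort

    return table1_cohort()
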