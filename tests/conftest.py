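import pytest

from t1crc_cea import default_life_table, default_parameter_set

# Accounting that reproduces the published base-case tables: costs discounted
# at 3%/yr, QALYs undiscounted (see docs/methods.md).
PUBLISHED = {"qaly_discount_rate": 0.0, "cost_discount_rate": 0.03}

# Published base-case results (unadjusted life-years, cost $, QALYs) per
# (class, strategy) cell.
PUBLISHED_TABLE = {
    ("class4", "ET"): (17.31, 41444, 16.24),
    ("class4", "LC"): (17.86, 65235, 16.45),
    ("class4", "OC"): (17.89, 68619, 16.22),
    ("class0", "ET"): (17.66, 51586, 16.50),
    ("class0", "LC"): (18.07, 71251, 16.61),
    ("class0", "OC"): (18.08, 73934, 16.36),
    ("msi_h", "ET"): (18.29, 68903, 16.97),
    ("msi_h", "LC"): (18.44, 81494, 16.89),
    ("msi_h", "OC"): (18.41, 82980, 16.61),
    ("class3", "ET"): (18.34, 70423, 17.01),
    ("class3", "LC"): (18.47, 82391, 16.91),
    ("class3", "OC"): (18.44, 83773, 16.63),
    ("class2", "ET"): (18.36, 70943, 17.03),
    ("class2", "LC"): (18.48, 82699, 16.92),
    ("class2", "OC"): (18.45, 84044, 16.64),
    ("class1", "ET"): (18.62, 77785, 17.22),
    ("class1", "LC"): (18.63, 86737, 17.03),
    ("class1", "OC"): (18.58, 87609, 16.74),
}


@pytest.fixture(scope="session")
def params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def lt():
    return default_life_table()


@pytest.fixture(scope="session")
def base_case_published(params, lt):
    """Full 18-cell base case in published-table accounting, computed once."""
    from t1crc_cea import base_case

    return base_case(params, lt, **PUBLISHED)
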