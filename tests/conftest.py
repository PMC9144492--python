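import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")

from greensolv.catalog import bundled_solutes, bundled_solvents


@pytest.fixture(scope="session")
def solutes():
    return {s.name: s for s in bundled_solutes()}


@pytest.fixture(scope="session")
def solvents():
    return {s.name: s for s in bundled_solvents()}


# Printed reference table for the four experimental solvent systems:
# (solvent, x2, EI default, EI without PCOP, rank default, rank without PCOP).
# Water anchors both rankings at rank 1 with EI 0.02.
PRINTED_EI_TABLE = [
    ("DMSO", 0.2, 6.09, 0.15, 12, 2),
    ("DMSO", 0.4, 8.69, 0.20, 13, 3),
    ("DMSO", 0.6, 10.10, 0.23, 14, 4),
    ("DMSO", 0.8, 11.00, 0.25, 15, 5),
    ("DMSO", 1.0, 11.70, 0.26, 16, 6),
    ("DMF", 0.2, 1.10, 1.10, 7, 12),
    ("DMF", 0.4, 1.58, 1.58, 8, 13),
    ("DMF", 0.6, 1.85, 1.85, 9, 14),
    ("DMF", 0.8, 2.03, 2.03, 10, 15),
    ("DMF", 1.0, 2.16, 2.16, 11, 16),
    ("4FM", 0.2, 0.32, 0.32, 2, 7),
    ("4FM", 0.4, 0.42, 0.41, 3, 8),
    ("4FM", 0.6, 0.46, 0.46, 4, 9),
    ("4FM", 0.8, 0.49, 0.49, 5, 10),
    ("4FM", 1.0, 0.51, 0.51, 6, 11),
]


@pytest.fixture(scope="session")
def printed_ei_table():
    return PRINTED_EI_TABLE
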