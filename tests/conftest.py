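import pandas as pd
import pytest

from safascore import (
    DEFAULT_EXCLUSIONS,
    CaptureTable,
    apply_exclusions,
    load_framework,
)


@pytest.fixture(scope="session")
def framework():
    """The bundled default framework (no exclusions applied)."""
    return load_framework()


@pytest.fixture(scope="session")
def excluded_framework(framework):
    """Default framework with the five default subtheme exclusions."""
    return apply_exclusions(framework, DEFAULT_EXCLUSIONS)


def make_capture_table(farm_id, rows):
    """rows: list of (taxon_group, species, count, endemic, at_risk, introduced)."""
    df = pd.DataFrame(
        rows,
        columns=["taxon_group", "species", "count", "endemic", "at_risk", "introduced"],
    )
    return CaptureTable(farm_id, df)


@pytest.fixture
def capture_table_factory():
    return make_capture_table


#: Published ranking-table valuations, in printed row order:
#: (farm, positive %, negative %, positive category, negative category)
TABLE3 = [
    ("Roble NS1", 67, 14, "best", "good"),
    ("Kampepem IS2", 62, 19, "best", "moderate"),
    ("Santa Teresa NS2", 57, 14, "best", "good"),
    ("Xhopel NS3", 48, 14, "good", "good"),
    ("UADY M2", 48, 14, "good", "good"),
    ("Kakalnah IS1", 48, 19, "good", "moderate"),
    ("Escalera M3", 33, 10, "moderate", "good"),
    ("Las Golondrinas IS3", 33, 14, "moderate", "good"),
    ("Ramonal M1", 24, 38, "limited", "unacceptable"),
]


@pytest.fixture(scope="session")
def table3_rows():
    return TABLE3
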