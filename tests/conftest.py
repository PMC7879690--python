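import pandas as pd
import pytest

from azscreen.count_model import CountTable, SampleSheet
from azscreen.synthetic_data import SynthConfig, generate


@pytest.fixture(scope="session")
def synth_default():
    """One dataset from the default synthetic study design."""
    return generate(SynthConfig(seed=11))


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        {"libA": [1, 3], "libB": [2, 4]},
        index=pd.Index(["c1", "c2"], name="contig_id"),
    )
    return CountTable(counts)


def make_ethylene_design(counts_by_lib, times_az150=(0, 3, 6, 9, 12),
                         times_comp=(0, 3, 6, 9), totals=None):
    """Build an ethylene-arm CountTable + SampleSheet from a dict
    library_id -> count list (library ids follow the AZ150_E0h naming)."""
    rows = []
    for t in times_az150:
        rows.append((f"AZ150_E{t}h", "AZ", 150, "ethylene", t))
    for t in times_comp:
        rows.append((f"AZ30_E{t}h", "AZ", 30, "ethylene", t))
    for t in times_comp:
        rows.append((f"P150_E{t}h", "P", 150, "ethylene", t))
    sheet = SampleSheet(
        pd.DataFrame(
            rows, columns=["library_id", "tissue", "stage_dap", "treatment", "time_h"]
        ).set_index("library_id")
    )
    counts = pd.DataFrame(counts_by_lib)
    counts.index = pd.Index(
        [f"g{i}" for i in range(len(counts))], name="contig_id"
    )
    table = CountTable(counts, library_totals=totals)
    return table, sheet


def make_natural_design(counts_by_lib, stages=(30, 120, 160), lengths_bp=1000,
                        totals=None, contig_ids=None):
    """Natural-arm CountTable (with lengths) + SampleSheet."""
    rows = [(f"AZnat_{s}DAP", "AZ", s, "field", pd.NA) for s in stages]
    sheet = SampleSheet(
        pd.DataFrame(
            rows, columns=["library_id", "tissue", "stage_dap", "treatment", "time_h"]
        ).set_index("library_id")
    )
    counts = pd.DataFrame(counts_by_lib)
    ids = contig_ids or [f"g{i}" for i in range(len(counts))]
    counts.index = pd.Index(ids, name="contig_id")
    lengths = pd.Series(lengths_bp, index=counts.index)
    table = CountTable(counts, library_totals=totals, lengths_bp=lengths)
    return table, sheet
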