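import numpy as np
import pandas as pd
import pytest

from mseqith.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient synthetic cohort reused by read-only tests."""
    cfg = SimulationConfig(n_patients=6, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def variant_fixture():
    """Three variants of one patient across two regions."""
    rows = []
    for rid, alts in (("R1", (30, 0, 12)), ("R2", (28, 25, 0))):
        for i, alt in enumerate(alts):
            rows.append(
                {
                    "patient_id": "PT1", "region_id": rid,
                    "chrom": "1", "pos": 1000 + i, "ref": "C", "alt": "T",
                    "ref_count": 100 - alt, "alt_count": alt,
                    "gene": f"G{i}", "effect": "missense",
                    "context": "A[C>T]G", "germline_flag": False,
                }
            )
    return pd.DataFrame(rows)


def make_segments(rows):
    """rows: (patient, region, chrom, start, end, major, minor)."""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "region_id", "chrom", "start", "end", "major_cn", "minor_cn"],
    )


@pytest.fixture()
def segment_rows():
    return make_segments
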