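import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mseqith import heterogeneity as het


# -- presence classification ---------------------------------------------------


def test_present_rule():
    assert het.is_present(2, 98)            # 2 alt reads at VAF 0.02
    assert not het.is_present(1, 99)        # below alt-read floor
    assert not het.is_present(2, 198)       # VAF 0.01 below floor
    assert not het.is_present(0, 0)


def test_assessable_power_rule():
    # depth 100 at expected clonal VAF 0.25: detection near-certain
    assert het.is_assessable(100, 0.25)
    # depth 2: P(alt >= 2) = 0.0625 << 0.95
    assert not het.is_assessable(2, 0.25)
    assert not het.is_assessable(0, 0.25)


def test_classify_presence_definitions():
    assert het.classify_presence(
        {"R1": True, "R2": True, "R3": True}, {"R1": True, "R2": True, "R3": True}
    ) == "ubiquitous"
    assert het.classify_presence(
        {"R1": True, "R2": False, "R3": False, "R4": False},
        {r: True for r in ("R1", "R2", "R3", "R4")},
    ) == "private"
    assert het.classify_presence(
        {"R1": True, "R2": True, "R3": False}, {"R1": True, "R2": True, "R3": True}
    ) == "shared"


def test_unassessable_region_excluded():
    """Present in 2/3 but the third region has no detection power: the call
    is made from the two assessable regions -> ubiquitous."""
    assert het.classify_presence(
        {"R1": True, "R2": True, "R3": False}, {"R1": True, "R2": True, "R3": False}
    ) == "ubiquitous"


def test_classify_presence_requires_presence_somewhere():
    with pytest.raises(ValueError):
        het.classify_presence({"R1": False}, {"R1": True})


def test_partition_identity_on_simulated_cohort(small_cohort):
    for p in small_cohort.patients:
        purities = p.purity
        somatic = p.variants[~p.variants["germline_flag"]]
        table = het.classify_presence_table(somatic, purities)
        counts = table["presence_class"].value_counts()
        total = counts.get("ubiquitous", 0) + counts.get("shared", 0) + counts.get("private", 0)
        assert total == len(table)
        assert set(table["presence_class"]) <= {"ubiquitous", "shared", "private"}


# -- burden --------------------------------------------------------------------


def test_snv_burden():
    assert het.snv_burden(30, 30.0) == 1.0
    assert het.snv_burden(0, 30.0) == 0.0
    with pytest.raises(ValueError):
        het.snv_burden(10, 0.0)


# -- FGA -----------------------------------------------------------------------


def test_fga_neutral_genome(segment_rows):
    seg = segment_rows([("PT", "R1", "1", 1, 3_000_000_000, 1, 1)])
    assert het.compute_fga(seg, 3_000_000_000) == 0.0


def test_fga_hand_case_30mb_gain(segment_rows):
    seg = segment_rows([("PT", "R1", "1", 1, 30_000_000, 2, 1)])
    assert het.compute_fga(seg, 3_000_000_000) == pytest.approx(0.01)


def test_fga_union_semantics(segment_rows):
    gain = ("1", 1, 30_000_000, 2, 1)
    one_region = segment_rows([("PT", "R1", *gain)])
    all_regions = segment_rows([("PT", r, *gain) for r in ("R1", "R2", "R3")])
    f1 = het.compute_fga(one_region, 3_000_000_000)
    f3 = het.compute_fga(all_regions, 3_000_000_000)
    assert f1 == f3 == pytest.approx(0.01)


def test_fga_empty_segments_error(segment_rows):
    with pytest.raises(ValueError, match="empty"):
        het.compute_fga(segment_rows([]), 1000)


def test_fga_wgd_baseline(segment_rows):
    # a 2+2 genome is neutral under a WGD call, altered without one
    seg = segment_rows([("PT", "R1", "1", 1, 1_000_000, 2, 2)])
    assert het.compute_fga(seg, 1_000_000, wgd_by_region={"R1": True}) == 0.0
    assert het.compute_fga(seg, 1_000_000) == 1.0


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    start=st.integers(min_value=1, max_value=10_000_000),
    length=st.integers(min_value=2, max_value=20_000_000),
    cut=st.floats(min_value=0.1, max_value=0.9),
)
def test_fga_invariant_to_segment_splitting(start, length, cut):
    """Splitting one altered segment into two abutting halves changes nothing."""
    from conftest import make_segments as segment_rows

    end = start + length - 1
    mid = start + max(1, int(length * cut)) - 1
    whole = segment_rows([("PT", "R1", "1", start, end, 2, 1)])
    split = segment_rows(
        [("PT", "R1", "1", start, mid, 2, 1), ("PT", "R1", "1", mid + 1, end, 2, 1)]
    )
    g = 3_000_000_000
    assert het.compute_fga(whole, g) == pytest.approx(het.compute_fga(split, g))


# -- heterogeneous SCNA fraction ----------------------------------------------


def test_het_fraction_identical_regions(segment_rows):
    seg = segment_rows(
        [("PT", r, "1", 1, 10_000_000, 2, 1) for r in ("R1", "R2")]
    )
    assert het.scna_heterogeneous_fraction(seg) == 0.0


def test_het_fraction_private_alteration(segment_rows):
    seg = segment_rows(
        [("PT", "R1", "1", 1, 10_000_000, 2, 1), ("PT", "R2", "2", 1, 5, 1, 1)]
    )
    assert het.scna_heterogeneous_fraction(seg) == 1.0


def test_het_fraction_mixed_hand_case(segment_rows):
    """10 Mb ubiquitous gain + 10 Mb private loss -> exactly half the altered
    bases are heterogeneous."""
    seg = segment_rows(
        [
            ("PT", "R1", "1", 1, 10_000_000, 2, 1),
            ("PT", "R2", "1", 1, 10_000_000, 2, 1),
            ("PT", "R1", "2", 1, 10_000_000, 1, 0),
        ]
    )
    assert het.scna_heterogeneous_fraction(seg) == pytest.approx(0.5)


def test_het_fraction_direction_aware(segment_rows):
    # gain in one region, loss of the same interval in the other: heterogeneous
    seg = segment_rows(
        [("PT", "R1", "1", 1, 10_000_000, 2, 1), ("PT", "R2", "1", 1, 10_000_000, 1, 0)]
    )
    assert het.scna_heterogeneous_fraction(seg) == 1.0


def test_het_fraction_single_region_undefined(segment_rows):
    seg = segment_rows([("PT", "R1", "1", 1, 10, 2, 1)])
    with pytest.warns(RuntimeWarning):
        assert np.isnan(het.scna_heterogeneous_fraction(seg))


def test_het_fraction_invariant_to_splitting(segment_rows):
    whole = segment_rows(
        [("PT", "R1", "1", 1, 10_000_000, 2, 1), ("PT", "R2", "1", 1, 10_000_000, 2, 1),
         ("PT", "R1", "2", 1, 4_000_000, 1, 0)]
    )
    split = segment_rows(
        [("PT", "R1", "1", 1, 6_000_000, 2, 1), ("PT", "R1", "1", 6_000_001, 10_000_000, 2, 1),
         ("PT", "R2", "1", 1, 10_000_000, 2, 1), ("PT", "R1", "2", 1, 4_000_000, 1, 0)]
    )
    assert het.scna_heterogeneous_fraction(whole) == pytest.approx(
        het.scna_heterogeneous_fraction(split)
    )


# -- WGD -----------------------------------------------------------------------


def test_wgd_calls(segment_rows):
    doubled = segment_rows([("PT", "R1", "1", 1, 100, 2, 2)])
    by_region, flag = het.call_wgd(doubled)
    assert by_region == {"R1": True} and flag == "homogeneous"

    diploid = segment_rows([("PT", "R1", "1", 1, 100, 1, 1)])
    by_region, flag = het.call_wgd(diploid)
    assert by_region == {"R1": False} and flag == "none"


def test_wgd_heterogeneous_flag(segment_rows):
    seg = segment_rows(
        [("PT", "R1", "1", 1, 100, 2, 2), ("PT", "R2", "1", 1, 100, 2, 2),
         ("PT", "R3", "1", 1, 100, 1, 1)]
    )
    _, flag = het.call_wgd(seg)
    assert flag == "heterogeneous"


# -- correlation ---------------------------------------------------------------


def test_correlation_perfect_line():
    x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    r, p = het.correlate_ith(x, x)
    assert r == pytest.approx(1.0)


def test_correlation_matches_direct_formula():
    x = np.array([0.12, 0.45, 0.33, 0.80, 0.05])
    y = np.array([0.50, 0.20, 0.65, 0.90, 0.10])
    r, _ = het.correlate_ith(x, y)
    oracle = float(
        np.sum((x - x.mean()) * (y - y.mean()))
        / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    )
    assert r == pytest.approx(oracle)


def test_correlation_null_simulation():
    rng = np.random.default_rng(42)
    hits = 0
    n_rep = 300
    for _ in range(n_rep):
        x = rng.uniform(size=50)
        y = rng.uniform(size=50)
        r, _ = het.correlate_ith(x, y)
        hits += abs(r) < 0.3
    assert hits / n_rep >= 0.95


def test_correlation_errors():
    with pytest.raises(ValueError, match="3 patients"):
        het.correlate_ith([0.1, 0.2], [0.1, 0.2])
    with pytest.raises(ValueError, match="variance"):
        het.correlate_ith([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])


# -- Mann-Whitney --------------------------------------------------------------


def _brute_force_mwu(x, y):
    """Independent oracle: full enumeration over group assignments."""
    combined = np.concatenate([x, y])
    n1 = len(x)
    def u_of(idx):
        sel = combined[list(idx)]
        rest = np.delete(combined, list(idx))
        return (sel[:, None] > rest[None, :]).sum() + 0.5 * (sel[:, None] == rest[None, :]).sum()
    u_obs = u_of(range(n1))
    us = [u_of(c) for c in itertools.combinations(range(len(combined)), n1)]
    us = np.array(us)
    p = min(1.0, 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean()))
    return u_obs, p


def test_mwu_canonical_separated_case():
    res = het.compare_groups([1, 2, 3], [4, 5, 6])
    assert res.u_statistic == 0.0
    assert res.p_value == pytest.approx(0.1)


def test_mwu_identical_groups():
    with pytest.warns(RuntimeWarning):
        res = het.compare_groups([2.0, 2.0], [2.0, 2.0])
    assert res.p_value == 1.0


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 6)])
def test_mwu_exact_matches_enumeration_oracle(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    for trial in range(5):
        # mix of tied and continuous data
        if trial % 2:
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
        else:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
        res = het.compare_groups(x, y)
        u_oracle, p_oracle = _brute_force_mwu(x, y)
        assert res.u_statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)


def test_mwu_exact_vs_asymptotic_consistency():
    rng = np.random.default_rng(0)
    x = rng.normal(0.0, 1.0, size=12)
    y = rng.normal(1.0, 1.0, size=13)
    exact = het.compare_groups(x, y, method="exact")
    approx = het.compare_groups(x, y, method="asymptotic")
    assert approx.p_value == pytest.approx(exact.p_value, rel=0.10)
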