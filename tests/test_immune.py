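import numpy as np
import pandas as pd
import pytest

from mseqith import immune_genomics as ig


def test_summarize_inif_extensive_rule():
    prof = ig.summarize_inif("PT", {"R1": 5.0, "R2": 25.0})
    assert prof.max_inif == 25.0
    assert prof.extensive


def test_summarize_inif_eligibility_rule():
    prof = ig.summarize_inif("PT", {"R1": 5.0, "R2": 7.0})
    assert not prof.digital_eligible
    prof = ig.summarize_inif("PT", {"R1": 5.0, "R2": 8.0})
    assert prof.digital_eligible  # at the threshold counts


def test_summarize_inif_mean_and_range():
    prof = ig.summarize_inif("PT", {"R1": 5.0, "R2": 10.0, "R3": 15.0, "R4": 25.0})
    assert prof.mean_inif == pytest.approx(13.75)
    assert prof.max_inif == 25.0
    assert min(prof.inif_by_region.values()) == 5.0


def test_summarize_inif_validation():
    with pytest.raises(ValueError, match="INIF"):
        ig.summarize_inif("PT", {"R1": 120.0})
    with pytest.raises(ValueError, match="region"):
        ig.summarize_inif("PT", {})


def test_cohort_threshold_is_median():
    assert ig.cohort_inif_threshold({"a": 4.0, "b": 8.0, "c": 30.0}) == 8.0


def test_ratio_single_region():
    ratio, per_region = ig.cd8_foxp3_ratio({"R1": (100, 50)})
    assert ratio == pytest.approx(2.0)
    assert per_region == {"R1": 2.0}


def test_ratio_pooling_is_sum_then_divide():
    ratio, _ = ig.cd8_foxp3_ratio({"R1": (100, 50), "R2": (200, 50)})
    assert ratio == pytest.approx(3.0)
    # pooling distinguishable from mean-of-ratios on an asymmetric fixture
    pooled, _ = ig.cd8_foxp3_ratio({"R1": (100, 50), "R2": (10, 50)})
    assert pooled == pytest.approx(110 / 100)
    mean_r, _ = ig.cd8_foxp3_ratio({"R1": (100, 50), "R2": (10, 50)}, pooling="mean")
    assert mean_r == pytest.approx((2.0 + 0.2) / 2)


def test_ratio_zero_foxp3_undefined():
    with pytest.warns(RuntimeWarning):
        ratio, _ = ig.cd8_foxp3_ratio({"R1": (100, 0)})
    assert ratio is None


def _variants(rows):
    base = {"patient_id": "PT", "region_id": "R1", "chrom": "3", "pos": 1,
            "ref": "C", "alt": "T", "ref_count": 50, "alt_count": 50,
            "gene": "", "effect": "missense", "context": "", "germline_flag": False,
            "protein_change": ""}
    df = pd.DataFrame([{**base, **r} for r in rows], columns=list(base))
    return df


def _segments(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "region_id", "chrom", "start", "end", "major_cn", "minor_cn"],
    )


def test_wnt_flag_from_ctnnb1_gof():
    v = _variants([{"gene": "CTNNB1", "protein_change": "p.T41A"}])
    s = _segments([("PT", "R1", "1", 1, 100, 1, 1)])
    flag, ev = ig.flag_wnt_activation(v, s)
    assert flag
    assert ev[0]["type"] == "CTNNB1_gof" and ev[0]["protein_change"] == "p.T41A"


def test_wnt_flag_negative_without_qualifying_events():
    v = _variants([{"gene": "CTNNB1", "protein_change": "p.A5V"}])  # not in GOF list
    s = _segments([("PT", "R1", "1", 1, 100, 1, 1)])
    flag, ev = ig.flag_wnt_activation(v, s)
    assert not flag and ev == []


def test_wnt_flag_apc_requires_homozygous_loss():
    apc_chrom, apc_start, apc_end = ig.DEFAULT_GENE_COORDS["APC"]
    het_loss = _segments([("PT", "R1", apc_chrom, apc_start - 10, apc_end + 10, 1, 0)])
    hom_loss = _segments([("PT", "R1", apc_chrom, apc_start - 10, apc_end + 10, 0, 0)])
    v = _variants([])
    assert not ig.flag_wnt_activation(v, het_loss)[0]
    assert ig.flag_wnt_activation(v, hom_loss)[0]


def test_wnt_flag_rspo2_amplification():
    chrom, start, end = ig.DEFAULT_GENE_COORDS["RSPO2"]
    amp = _segments([("PT", "R1", chrom, start, end, 3, 1)])
    flag, ev = ig.flag_wnt_activation(_variants([]), amp)
    assert flag and ev[0]["type"] == "RSPO2_amplification"


def test_wnt_flag_monotone_in_evidence():
    """Adding a qualifying event never turns a true flag false."""
    v = _variants([{"gene": "CTNNB1", "protein_change": "p.S33P"}])
    chrom, start, end = ig.DEFAULT_GENE_COORDS["RSPO2"]
    s0 = _segments([("PT", "R1", "1", 1, 100, 1, 1)])
    s1 = _segments([("PT", "R1", chrom, start, end, 3, 1)])
    assert ig.flag_wnt_activation(v, s0)[0]
    flag, ev = ig.flag_wnt_activation(v, s1)
    assert flag and len(ev) >= 2


def test_mmrd_germline_variant_plus_deletion():
    chrom, start, end = ig.DEFAULT_GENE_COORDS["MSH6"]
    v = _variants([{"gene": "MSH6", "germline_flag": True, "chrom": chrom, "pos": start + 10}])
    s = _segments([("PT", "R1", chrom, start - 1000, end + 1000, 1, 0)])
    flag, ev, mono = ig.flag_mmrd(v, s)
    assert flag
    mechanisms = {e["mechanism"] for e in ev}
    assert "germline_variant" in mechanisms and "deletion" in mechanisms


def test_mmrd_two_somatic_deletions():
    chrom, start, end = ig.DEFAULT_GENE_COORDS["MSH2"]
    s = _segments(
        [("PT", "R1", chrom, start - 5_000_000, end + 5_000_000, 1, 0),
         ("PT", "R2", chrom, start + 100, start + 5_100, 0, 0)]
    )
    flag, ev, _ = ig.flag_mmrd(_variants([]), s)
    assert flag


def test_mmrd_heterozygous_deletion_alone_is_monoallelic():
    chrom, start, end = ig.DEFAULT_GENE_COORDS["MSH2"]
    s = _segments([("PT", "R1", chrom, start - 1000, end + 1000, 1, 0)])
    flag, ev, mono = ig.flag_mmrd(_variants([]), s)
    assert not flag
    assert len(mono) == 1 and mono[0]["gene"] == "MSH2"


def test_mmrd_same_truncal_deletion_in_all_regions_counts_once():
    chrom, start, end = ig.DEFAULT_GENE_COORDS["MLH1"]
    s = _segments(
        [("PT", r, chrom, start - 1000, end + 1000, 1, 0) for r in ("R1", "R2", "R3")]
    )
    flag, _, mono = ig.flag_mmrd(_variants([]), s)
    assert not flag and len(mono) == 1


def test_neoantigen_association_rank_identity():
    inif = {f"P{i}": float(i) for i in range(10)}
    burden = {f"P{i}": float(i * 7) for i in range(10)}
    clonal = {f"P{i}": float(i * 3.5) for i in range(10)}  # constant multiple
    out = ig.associate_neoantigen_inif(burden, clonal, inif)
    assert out["total_burden"]["rho"] == pytest.approx(1.0)
    # rank invariance: scaled burden gives the identical rho
    assert out["clonal_burden"]["rho"] == pytest.approx(out["total_burden"]["rho"])


def test_neoantigen_association_needs_three_patients():
    with pytest.raises(ValueError, match="3 patients"):
        ig.associate_neoantigen_inif({"a": 1}, {"a": 1}, {"a": 1})


def test_compare_ratio_by_wnt_eligibility_filter():
    ratios = {f"P{i}": float(i + 1) for i in range(8)}
    wnt = {f"P{i}": i < 4 for i in range(8)}
    eligible = {f"P{i}": i not in (0, 7) for i in range(8)}
    res = ig.compare_ratio_by_wnt(ratios, wnt, eligible)
    assert res.n1 + res.n2 == 6  # two patients filtered out


def test_compare_ratio_by_wnt_requires_both_groups():
    with pytest.raises(ValueError, match="non-empty"):
        ig.compare_ratio_by_wnt({"a": 1.0}, {"a": False}, {"a": True})
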