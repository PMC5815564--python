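"""Immune-infiltrate summaries and genotype–immune association tests.

Consumes per-region immune counts from the sample sheet — INIF (percent of
nucleated cells that are infiltrating T cells) and CD8+/CD4+/FOXP3+ cell
counts — together with the genomic tables, and produces:

* per-patient INIF summaries with the *extensive* flag (any region above
  20%) and the *digital-analysis-eligible* flag (any region at or above the
  cohort-median INIF threshold, default 8);
* pooled CD8+/FOXP3+ ratios (sum counts across eligible regions, then
  divide — robust to zero FOXP3 counts in single regions);
* pathway flags: Wnt activation (gain-of-function CTNNB1 variant, RSPO2
  amplification, or homozygous deletion of APC/RNF43/ZNRF3) and
  mismatch-repair deficiency (two hits on one MMR gene; single hits are
  surfaced as monoallelic, not MMRD);
* Spearman association of neoantigen burdens with INIF, and the CD8/FOXP3
  ratio comparison between Wnt-activated and wild-type patients (restricted
  to digital-eligible patients, via the shared Mann–Whitney implementation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .heterogeneity import GroupComparison, compare_groups

__all__ = [
    "ImmuneProfile",
    "PathwayFlags",
    "DEFAULT_GENE_COORDS",
    "WNT_GOF_VARIANTS",
    "MMR_GENES",
    "summarize_inif",
    "cd8_foxp3_ratio",
    "flag_wnt_activation",
    "flag_mmrd",
    "associate_neoantigen_inif",
    "compare_ratio_by_wnt",
]

#: Maximal per-region INIF above this percent marks *extensive* infiltrate.
EXTENSIVE_INIF_PERCENT = 20.0

#: Default eligibility threshold for digital image analysis (cohort median).
DEFAULT_INIF_THRESHOLD = 8.0

#: CTNNB1 exon-3 gain-of-function protein changes shipped by default;
#: extensible via the gof_variants argument.
WNT_GOF_VARIANTS = ["p.S33P", "p.S33C", "p.T41A"]

#: Mismatch-repair genes screened for biallelic inactivation.
MMR_GENES = ["MLH1", "MSH2", "MSH6", "PMS2"]

#: Default gene intervals (GRCh37, 1-based inclusive); configuration, not
#: biology baked into code — override with a BED-like TSV via read_gene_coords.
DEFAULT_GENE_COORDS = {
    "APC": ("5", 112_043_195, 112_181_936),
    "RNF43": ("17", 56_431_037, 56_494_956),
    "ZNRF3": ("22", 29_278_025, 29_449_835),
    "RSPO2": ("8", 108_911_544, 109_095_052),
    "MLH1": ("3", 37_034_841, 37_107_380),
    "MSH2": ("2", 47_630_206, 47_710_367),
    "MSH6": ("2", 48_010_221, 48_034_092),
    "PMS2": ("7", 6_012_870, 6_048_737),
}


@dataclass
class ImmuneProfile:
    patient_id: str
    inif_by_region: dict[str, float]
    max_inif: float
    mean_inif: float
    extensive: bool
    digital_eligible: bool
    cd8_foxp3_ratio: float | None = None
    ratio_by_region: dict[str, float] = field(default_factory=dict)


@dataclass
class PathwayFlags:
    patient_id: str
    wnt_activated: bool = False
    wnt_evidence: list = field(default_factory=list)
    mmrd: bool = False
    mmrd_evidence: list = field(default_factory=list)
    mmrd_monoallelic: list = field(default_factory=list)


def read_gene_coords(path) -> dict[str, tuple[str, int, int]]:
    """Read gene intervals from a BED-like TSV (gene, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("gene", "chrom", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"gene coordinate file missing column(s): {missing}")
    return {
        row["gene"]: (row["chrom"], int(row["start"]), int(row["end"]))
        for _, row in df.iterrows()
    }


def summarize_inif(
    patient_id: str,
    inif_by_region: dict[str, float],
    *,
    eligibility_threshold: float = DEFAULT_INIF_THRESHOLD,
) -> ImmuneProfile:
    """Per-patient INIF summary with extensive and digital-eligibility flags."""
    if not inif_by_region:
        raise ValueError("need at least one region with an INIF value")
    vals = np.array(list(inif_by_region.values()), dtype=float)
    if np.any(vals < 0) or np.any(vals > 100):
        raise ValueError(f"INIF percent outside [0, 100] for {patient_id}")
    return ImmuneProfile(
        patient_id=patient_id,
        inif_by_region=dict(inif_by_region),
        max_inif=float(vals.max()),
        mean_inif=float(vals.mean()),
        extensive=bool(vals.max() > EXTENSIVE_INIF_PERCENT),
        digital_eligible=bool(vals.max() >= eligibility_threshold),
    )


def cohort_inif_threshold(max_inif_by_patient: dict[str, float]) -> float:
    """Recompute the digital-eligibility threshold as the cohort median of
    per-patient maximal INIF."""
    return float(np.median(list(max_inif_by_patient.values())))


def cd8_foxp3_ratio(
    counts_by_region: dict[str, tuple[int, int]],
    *,
    pooling: str = "sum",
) -> tuple[float | None, dict[str, float]]:
    """Patient-level CD8+/FOXP3+ ratio from per-region (cd8, foxp3) counts.

    Default pooling sums counts across regions before dividing; per-region
    ratios are returned alongside (undefined regions omitted). A zero
    pooled FOXP3 count yields None with a warning — the patient is excluded
    from ratio-based tests.
    """
    per_region = {}
    cd8_total = foxp3_total = 0
    for rid, (cd8, foxp3) in counts_by_region.items():
        if cd8 < 0 or foxp3 < 0:
            raise ValueError(f"negative immune counts in region {rid}")
        cd8_total += cd8
        foxp3_total += foxp3
        if foxp3 > 0:
            per_region[rid] = cd8 / foxp3
    if pooling == "sum":
        if foxp3_total == 0:
            warnings.warn("pooled FOXP3 count is zero; ratio undefined", RuntimeWarning)
            return None, per_region
        return cd8_total / foxp3_total, per_region
    if pooling == "mean":
        if not per_region:
            warnings.warn("no region with FOXP3 > 0; ratio undefined", RuntimeWarning)
            return None, per_region
        return float(np.mean(list(per_region.values()))), per_region
    raise ValueError(f"unknown pooling {pooling!r}")


def _segments_overlapping_gene(
    segments: pd.DataFrame, coords: tuple[str, int, int]
) -> pd.DataFrame:
    chrom, start, end = coords
    seg = segments[segments["chrom"] == chrom]
    return seg[(seg["start"] <= end) & (seg["end"] >= start)]


def flag_wnt_activation(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    *,
    gene_coords: dict[str, tuple[str, int, int]] | None = None,
    gof_variants: list[str] | None = None,
    amp_threshold: int | None = None,
    wgd_by_region: dict[str, bool] | None = None,
) -> tuple[bool, list]:
    """Somatic Wnt-pathway activation flag for one patient.

    True iff any region shows (a) a CTNNB1 variant whose ``protein_change``
    is in the configured exon-3 gain-of-function list, (b) RSPO2 total copy
    number at or above the amplification threshold — by default twice the
    region's ploidy baseline (4, or 8 in whole-genome-doubled regions), or
    (c) a homozygous deletion (total CN 0) overlapping APC, RNF43 or ZNRF3.
    Evidence records are returned with the flag.
    """
    gene_coords = gene_coords or DEFAULT_GENE_COORDS
    wgd_by_region = wgd_by_region or {}
    gof = set(gof_variants if gof_variants is not None else WNT_GOF_VARIANTS)
    evidence = []

    ctnnb1 = variants[(variants["gene"] == "CTNNB1") & (~variants["germline_flag"])]
    if "protein_change" in ctnnb1.columns:
        hits = ctnnb1[ctnnb1["protein_change"].isin(gof)]
        for _, row in hits.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]).iterrows():
            evidence.append(
                {"type": "CTNNB1_gof", "protein_change": row["protein_change"],
                 "chrom": row["chrom"], "pos": int(row["pos"])}
            )

    for gene, rule in (("RSPO2", "amp"), ("APC", "homdel"), ("RNF43", "homdel"), ("ZNRF3", "homdel")):
        if gene not in gene_coords:
            raise ValueError(f"gene coordinates missing from configuration: {gene}")
        over = _segments_overlapping_gene(segments, gene_coords[gene])
        total = over["major_cn"] + over["minor_cn"]
        if rule == "amp":
            if amp_threshold is None:
                baselines = over["region_id"].map(
                    lambda r: 8 if wgd_by_region.get(r) else 4
                )
            else:
                baselines = pd.Series(amp_threshold, index=over.index)
            hit = over[total >= baselines]
            kind = "RSPO2_amplification"
        else:
            hit = over[total == 0]
            kind = f"{gene}_homozygous_deletion"
        for _, row in hit.iterrows():
            evidence.append(
                {"type": kind, "region_id": row["region_id"],
                 "chrom": row["chrom"], "start": int(row["start"]), "end": int(row["end"]),
                 "total_cn": int(total.loc[row.name])}
            )
    return bool(evidence), evidence


def flag_mmrd(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    *,
    mmr_genes: list[str] | None = None,
    gene_coords: dict[str, tuple[str, int, int]] | None = None,
) -> tuple[bool, list, list]:
    """Mismatch-repair deficiency flag: two independent hits on one MMR gene.

    A hit is a deleterious (non-silent) variant — germline or somatic — in
    the gene, or a distinct deletion segment overlapping it with complete
    loss of one allele (minor CN 0 below a heterozygous state); a homozygous
    deletion (major CN also 0) counts as both alleles lost. The same
    truncal deletion observed in several regions is one event. Returns
    (mmrd, evidence, monoallelic) where ``monoallelic`` lists genes with
    exactly one hit — explicitly surfaced, not MMRD.
    """
    mmr_genes = mmr_genes or MMR_GENES
    gene_coords = gene_coords or DEFAULT_GENE_COORDS
    evidence = []
    monoallelic = []
    any_biallelic = False
    for gene in mmr_genes:
        hits = []
        gvar = variants[(variants["gene"] == gene) & (variants["effect"] != "silent")]
        for _, row in gvar.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]).iterrows():
            origin = "germline" if row["germline_flag"] else "somatic"
            hits.append(
                {"gene": gene, "mechanism": f"{origin}_variant",
                 "chrom": row["chrom"], "pos": int(row["pos"]), "effect": row["effect"]}
            )
        if gene in gene_coords:
            over = _segments_overlapping_gene(segments, gene_coords[gene])
            dels = over[over["minor_cn"] == 0]
            dels = dels.drop_duplicates(subset=["chrom", "start", "end"])
            for _, row in dels.iterrows():
                cn = int(row["major_cn"] + row["minor_cn"])
                hit = {"gene": gene, "mechanism": "deletion",
                       "chrom": row["chrom"], "start": int(row["start"]),
                       "end": int(row["end"]), "total_cn": cn}
                hits.append(hit)
                if cn == 0:  # homozygous: both alleles lost by one event
                    hits.append({**hit, "mechanism": "deletion_second_allele"})
        if len(hits) >= 2:
            any_biallelic = True
            evidence.extend(hits)
        elif len(hits) == 1:
            monoallelic.append(hits[0])
    return any_biallelic, evidence, monoallelic


def associate_neoantigen_inif(
    burden_by_patient: dict[str, float],
    clonal_burden_by_patient: dict[str, float],
    max_inif_by_patient: dict[str, float],
) -> dict[str, dict[str, float]]:
    """Spearman correlation of (clonal) neoantigen burden with maximal INIF."""
    patients = sorted(
        set(burden_by_patient) & set(clonal_burden_by_patient) & set(max_inif_by_patient)
    )
    if len(patients) < 3:
        raise ValueError("need >= 3 patients for the neoantigen/INIF association")
    inif = np.array([max_inif_by_patient[p] for p in patients], dtype=float)
    out = {}
    for name, burdens in (
        ("total_burden", burden_by_patient),
        ("clonal_burden", clonal_burden_by_patient),
    ):
        x = np.array([burdens[p] for p in patients], dtype=float)
        rho, p = stats.spearmanr(x, inif)
        out[name] = {"rho": float(rho), "p_value": float(p), "n": len(patients)}
    return out


def compare_ratio_by_wnt(
    ratio_by_patient: dict[str, float | None],
    wnt_by_patient: dict[str, bool],
    eligible_by_patient: dict[str, bool],
) -> GroupComparison:
    """CD8+/FOXP3+ ratio: Wnt-activated vs wild-type, digital-eligible only.

    Patients below the INIF eligibility threshold or with undefined ratios
    are excluded before testing; the comparison routes through the shared
    Mann–Whitney implementation.
    """
    wnt_vals, wt_vals = [], []
    for pid, ratio in ratio_by_patient.items():
        if ratio is None or not eligible_by_patient.get(pid, False):
            continue
        (wnt_vals if wnt_by_patient.get(pid, False) else wt_vals).append(ratio)
    if not wnt_vals or not wt_vals:
        raise ValueError("both Wnt-activated and wild-type groups must be non-empty")
    return compare_groups(wnt_vals, wt_vals, labels=("wnt_activated", "wild_type"))
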