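"""End-to-end cohort analysis: glue over the per-stage modules.

Runs, for each patient: presence classification, burden, FGA and
heterogeneous-SCNA fraction, WGD calls, CCF clustering, clone-tree
reconstruction, parallel-evolution detection, signature attribution by
clonality, pathway flags and immune summaries; then the cohort-level
statistics (group comparisons, ITH correlation, locus enrichment,
ratio-by-Wnt, neoantigen association).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    ccf_clustering,
    heterogeneity,
    immune_genomics,
    phylogeny_parallel,
    scna_enrichment,
    signatures,
)
from .io_formats import SampleSheet, SegmentLookup
from .synthetic_data import DEFAULT_GENOME

__all__ = ["PatientAnalysis", "CohortAnalysis", "analyze_patient", "analyze_cohort"]


@dataclass
class PatientAnalysis:
    profile: heterogeneity.PatientProfile
    classified: pd.DataFrame  # one row per mutation with presence_class
    clustering: ccf_clustering.ClusteringResult | None
    trees: list[phylogeny_parallel.CloneTree]
    parallel_events: list[phylogeny_parallel.ParallelEvent]
    signature_fits: dict[str, signatures.SignatureFit | None]
    flags: immune_genomics.PathwayFlags
    immune: immune_genomics.ImmuneProfile | None


@dataclass
class CohortAnalysis:
    patients: dict[str, PatientAnalysis]
    cohort: dict = field(default_factory=dict)


def _mutation_ids(variants: pd.DataFrame) -> pd.Series:
    if "mutation_id" in variants.columns:
        return variants["mutation_id"]
    return (
        variants["patient_id"].astype(str)
        + ":" + variants["chrom"].astype(str)
        + ":" + variants["pos"].astype(str)
        + ":" + variants["ref"] + ">" + variants["alt"]
    )


def analyze_patient(
    patient_id: str,
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    sheet: SampleSheet,
    *,
    genome_length: int | None = None,
    target_mb: float = 30.0,
    catalogue: pd.DataFrame | None = None,
    max_clusters: int = 6,
    n_restarts: int = 4,
    max_mutations_for_clustering: int = 400,
    seed: int = 0,
    run_clustering: bool = True,
) -> PatientAnalysis:
    """Full single-patient analysis from the three canonical inputs."""
    genome_length = genome_length or sum(l for _, l in DEFAULT_GENOME)
    catalogue = catalogue if catalogue is not None else signatures.builtin_catalogue()
    variants = variants.copy()
    variants["mutation_id"] = _mutation_ids(variants)
    somatic = variants[~variants["germline_flag"]]
    purities = {
        rid: sheet.purity(patient_id, rid) for rid in sheet.region_ids(patient_id)
    }
    region_ids = sorted(purities)

    # presence classes and burden
    classified = heterogeneity.classify_presence_table(somatic, purities)
    mid_by_key = somatic.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]).set_index(
        ["chrom", "pos", "ref", "alt"]
    )["mutation_id"]
    classified["mutation_id"] = [
        mid_by_key.loc[(r["chrom"], r["pos"], r["ref"], r["alt"])]
        for _, r in classified.iterrows()
    ]
    counts = classified["presence_class"].value_counts()
    burden = heterogeneity.snv_burden(len(classified), target_mb)

    # SCNA metrics
    wgd_by_region, wgd_patient = heterogeneity.call_wgd(segments)
    fga = heterogeneity.compute_fga(segments, genome_length, wgd_by_region=wgd_by_region)
    if len(region_ids) >= 2:
        het_frac = heterogeneity.scna_heterogeneous_fraction(
            segments, wgd_by_region=wgd_by_region
        )
    else:
        het_frac = float("nan")

    # clustering and trees
    clustering = None
    trees: list[phylogeny_parallel.CloneTree] = []
    parallel_events: list[phylogeny_parallel.ParallelEvent] = []
    assignment: dict[str, int] = {}
    if run_clustering and len(classified):
        alt, depth, cn_total, cn_major, mids = _count_matrices(
            somatic, region_ids, segments
        )
        rng = np.random.default_rng(seed)
        if len(mids) > max_mutations_for_clustering:
            pick = np.sort(
                rng.choice(len(mids), max_mutations_for_clustering, replace=False)
            )
        else:
            pick = np.arange(len(mids))
        pur = np.array([purities[r] for r in region_ids])
        clustering = ccf_clustering.cluster_mutations(
            alt[pick], depth[pick], pur, cn_total[pick], cn_major[pick],
            max_clusters=max_clusters, n_restarts=n_restarts,
            seed=seed, mutation_ids=[mids[i] for i in pick],
        )
        full_ids = ccf_clustering.posterior_assignments(
            alt, depth, pur, cn_total, cn_major, clustering.clusters
        )
        assignment = dict(zip(mids, (int(x) for x in full_ids)))
        try:
            trees = phylogeny_parallel.build_clone_tree(
                clustering.clusters, patient_id=patient_id
            )
        except ValueError as exc:
            warnings.warn(f"{patient_id}: clone tree not built ({exc})", RuntimeWarning)
        if trees:
            union = somatic.drop_duplicates(subset=["mutation_id"])
            parallel_events = phylogeny_parallel.detect_parallel_evolution(
                union, assignment, trees[0],
                gene_sets={"wnt_pathway": phylogeny_parallel.WNT_PATHWAY_GENES},
            )

    # signatures by clonality
    signature_fits = signatures.attribute_by_clonality(classified, catalogue)

    # pathway flags (germline rows participate in MMRD evidence)
    wnt, wnt_ev = immune_genomics.flag_wnt_activation(
        variants, segments, wgd_by_region=wgd_by_region
    )
    mmrd, mmrd_ev, mono = immune_genomics.flag_mmrd(variants, segments)
    flags = immune_genomics.PathwayFlags(
        patient_id=patient_id, wnt_activated=wnt, wnt_evidence=wnt_ev,
        mmrd=mmrd, mmrd_evidence=mmrd_ev, mmrd_monoallelic=mono,
    )

    # immune summary
    immune = None
    regions_meta = sheet.patients[patient_id]["regions"]
    inif = {
        rid: rec["inif_percent"]
        for rid, rec in regions_meta.items()
        if rec.get("inif_percent") is not None
    }
    if inif:
        immune = immune_genomics.summarize_inif(patient_id, inif)
        counts_by_region = {
            rid: (rec.get("cd8", 0), rec.get("foxp3", 0))
            for rid, rec in regions_meta.items()
            if rec.get("cd8") is not None and rec.get("foxp3") is not None
        }
        if counts_by_region:
            ratio, per_region = immune_genomics.cd8_foxp3_ratio(counts_by_region)
            immune.cd8_foxp3_ratio = ratio
            immune.ratio_by_region = per_region

    profile = heterogeneity.PatientProfile(
        patient_id=patient_id,
        n_regions=len(region_ids),
        n_ubiquitous=int(counts.get("ubiquitous", 0)),
        n_shared=int(counts.get("shared", 0)),
        n_private=int(counts.get("private", 0)),
        burden_per_mb=burden,
        fga=fga,
        heterogeneous_scna_fraction=het_frac,
        wgd_patient=wgd_patient,
        wgd_by_region=wgd_by_region,
        clinical_group=sheet.group(patient_id),
        gleason=sheet.patients[patient_id].get("gleason"),
    )
    return PatientAnalysis(
        profile=profile, classified=classified, clustering=clustering,
        trees=trees, parallel_events=parallel_events,
        signature_fits=signature_fits, flags=flags, immune=immune,
    )


def _count_matrices(
    somatic: pd.DataFrame, region_ids: list[str], segments: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(M, R) alt/depth/CN matrices over the patient's mutation union.

    Mutations not assayed in a region get depth 0 there (no likelihood
    contribution beyond the zero-depth binomial, which is constant).
    """
    union = somatic.drop_duplicates(subset=["mutation_id"])
    mids = union["mutation_id"].tolist()
    pos_of = {m: i for i, m in enumerate(mids)}
    M, R = len(mids), len(region_ids)
    alt = np.zeros((M, R))
    depth = np.zeros((M, R))
    cn_total = np.full((M, R), 2.0)
    cn_major = np.full((M, R), 1.0)
    lookup = SegmentLookup(segments)
    rix = {r: j for j, r in enumerate(region_ids)}
    for _, row in somatic.iterrows():
        i = pos_of[row["mutation_id"]]
        j = rix.get(row["region_id"])
        if j is None:
            continue
        alt[i, j] = row["alt_count"]
        depth[i, j] = row["alt_count"] + row["ref_count"]
    for _, row in union.iterrows():
        i = pos_of[row["mutation_id"]]
        for r, j in rix.items():
            tot, maj = lookup.at(r, row["chrom"], int(row["pos"]))
            cn_total[i, j] = max(tot, 1)  # sites on homozygous deletions
            cn_major[i, j] = max(maj, 1)  # still get a defined (inert) term
    return alt, depth, cn_total, cn_major, mids


def analyze_cohort(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    sheet: SampleSheet,
    *,
    genome: list[tuple[str, int]] | None = None,
    target_mb: float = 30.0,
    catalogue: pd.DataFrame | None = None,
    loci: list[scna_enrichment.Locus] | None = None,
    run_clustering: bool = True,
    run_permutation: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
) -> CohortAnalysis:
    """Analyse every patient in the sheet and compute cohort statistics."""
    genome = genome or list(DEFAULT_GENOME)
    genome_length = sum(l for _, l in genome)
    loci = loci if loci is not None else list(scna_enrichment.DEFAULT_LOCI)
    sheet.check_regions_covered(variants)
    sheet.check_regions_covered(segments)

    rng = np.random.default_rng(seed)
    patients: dict[str, PatientAnalysis] = {}
    for pid in sorted(sheet.patients):
        pv = variants[variants["patient_id"] == pid]
        ps = segments[segments["patient_id"] == pid]
        if len(pv) == 0 and len(ps) == 0:
            continue
        patients[pid] = analyze_patient(
            pid, pv, ps, sheet,
            genome_length=genome_length, target_mb=target_mb,
            catalogue=catalogue, seed=int(rng.integers(0, 2**31 - 1)),
            run_clustering=run_clustering,
        )

    cohort: dict = {}
    pids = sorted(patients)
    group_of = {pid: sheet.group(pid) for pid in pids}
    profiles = {pid: patients[pid].profile for pid in pids}

    # group contrasts on FGA, burden, heterogeneity metrics
    for metric, getter in (
        ("fga", lambda p: p.fga),
        ("burden_per_mb", lambda p: p.burden_per_mb),
        ("heterogeneous_scna_fraction", lambda p: p.heterogeneous_scna_fraction),
        ("non_ubiquitous_fraction", lambda p: p.non_ubiquitous_fraction),
    ):
        g1 = [getter(profiles[p]) for p in pids if group_of[p] == "mHNPC"]
        g2 = [getter(profiles[p]) for p in pids if group_of[p] == "hrlPC"]
        g1 = [v for v in g1 if not np.isnan(v)]
        g2 = [v for v in g2 if not np.isnan(v)]
        if g1 and g2:
            cmp = heterogeneity.compare_groups(g1, g2, labels=("mHNPC", "hrlPC"))
            cohort[f"{metric}_group_test"] = {
                "u": cmp.u_statistic, "p_value": cmp.p_value,
                "mean_mHNPC": cmp.means[0], "mean_hrlPC": cmp.means[1],
                "n": (cmp.n1, cmp.n2), "method": cmp.method,
            }
        cohort[f"{metric}_median"] = float(np.median(g1 + g2)) if (g1 or g2) else None

    # SNV vs SCNA heterogeneity correlation
    x = np.array([profiles[p].non_ubiquitous_fraction for p in pids])
    y = np.array([profiles[p].heterogeneous_scna_fraction for p in pids])
    try:
        r, p = heterogeneity.correlate_ith(x, y)
        cohort["ith_correlation"] = {"r": r, "p_value": p}
    except ValueError as exc:
        cohort["ith_correlation"] = {"error": str(exc)}

    # locus enrichment
    seg_by_patient = {
        pid: segments[segments["patient_id"] == pid] for pid in pids
    }
    locus_results = {}
    for locus in loci:
        status = {
            pid: scna_enrichment.call_locus_event(seg_by_patient[pid], locus).status
            for pid in pids
        }
        entry: dict = {"status_by_patient": status}
        try:
            odds, fisher_p, table = scna_enrichment.enrichment_test(status, group_of)
            entry.update({"odds_ratio": odds, "fisher_p": fisher_p, "table": table})
        except ValueError as exc:
            entry["error"] = str(exc)
        if run_permutation:
            perm = scna_enrichment.burden_controlled_enrichment(
                seg_by_patient, locus, group_of, genome,
                n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)),
            )
            entry["burden_controlled_p"] = perm["p_value"]
        locus_results[locus.locus_id] = entry
    cohort["locus_enrichment"] = locus_results

    # immune associations
    eligible = {}
    ratios = {}
    wnt = {}
    max_inif = {}
    for pid in pids:
        pa = patients[pid]
        wnt[pid] = pa.flags.wnt_activated
        if pa.immune is not None:
            eligible[pid] = pa.immune.digital_eligible
            max_inif[pid] = pa.immune.max_inif
            ratios[pid] = pa.immune.cd8_foxp3_ratio
    if max_inif:
        cohort["inif_median_threshold"] = immune_genomics.cohort_inif_threshold(max_inif)
    try:
        cmp = immune_genomics.compare_ratio_by_wnt(ratios, wnt, eligible)
        cohort["cd8_foxp3_by_wnt"] = {
            "u": cmp.u_statistic, "p_value": cmp.p_value,
            "mean_wnt": cmp.means[0], "mean_wt": cmp.means[1],
            "n": (cmp.n1, cmp.n2),
        }
    except ValueError as exc:
        cohort["cd8_foxp3_by_wnt"] = {"error": str(exc)}

    burdens = {
        pid: sheet.patients[pid].get("neoantigen_burden") for pid in pids
    }
    clonal = {
        pid: sheet.patients[pid].get("clonal_neoantigen_burden") for pid in pids
    }
    burdens = {k: v for k, v in burdens.items() if v is not None}
    clonal = {k: v for k, v in clonal.items() if v is not None}
    if len(set(burdens) & set(clonal) & set(max_inif)) >= 3:
        cohort["neoantigen_inif"] = immune_genomics.associate_neoantigen_inif(
            burdens, clonal, max_inif
        )

    # cohort-wide mutation partition totals
    cohort["snv_partition"] = {
        "ubiquitous": int(sum(profiles[p].n_ubiquitous for p in pids)),
        "shared": int(sum(profiles[p].n_shared for p in pids)),
        "private": int(sum(profiles[p].n_private for p in pids)),
    }
    cohort["snv_partition"]["total"] = sum(cohort["snv_partition"].values())
    return CohortAnalysis(patients=patients, cohort=cohort)
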