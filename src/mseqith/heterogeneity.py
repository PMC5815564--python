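"""Per-patient SNV and SCNA intratumoural heterogeneity metrics.

Covers: presence classification of mutations across regions (ubiquitous /
shared / private, with a detection-power rule so low-depth regions cannot
inflate the private count), exonic mutation burden per megabase, fraction
of genome altered (FGA) under union-across-regions semantics, the fraction
of altered bases that are heterogeneous between regions, whole-genome
doubling calls, and the cohort-level statistics used throughout the
package (Pearson correlation of ITH metrics, Mann–Whitney U group
comparison with an exact small-sample path).

All interval arithmetic here is half-open 0-based; segment tables arrive in
1-based inclusive coordinates (the on-disk convention) and are converted on
entry.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientProfile",
    "GroupComparison",
    "is_present",
    "is_assessable",
    "classify_presence",
    "classify_presence_table",
    "snv_burden",
    "compute_fga",
    "scna_heterogeneous_fraction",
    "call_wgd",
    "correlate_ith",
    "compare_groups",
]

#: Presence rule: a mutation is called present in a region when it has at
#: least this many alt reads ...
MIN_ALT_READS = 2
#: ... and at least this VAF.
MIN_VAF = 0.02

#: A region is assessable for absence only if, were the mutation clonal
#: there, the presence rule would fire with at least this probability.
POWER_THRESHOLD = 0.95

#: Diploid copy-neutral total copy number; doubled genomes use 4.
NEUTRAL_CN = 2
WGD_NEUTRAL_CN = 4

#: Region-level WGD call: fraction of covered genome with major_cn >= 2.
WGD_MAJOR_FRACTION = 0.5


@dataclass
class PatientProfile:
    """Aggregate per-patient heterogeneity record."""

    patient_id: str
    n_regions: int
    n_ubiquitous: int = 0
    n_shared: int = 0
    n_private: int = 0
    burden_per_mb: float = float("nan")
    fga: float = float("nan")
    heterogeneous_scna_fraction: float = float("nan")
    wgd_patient: str = "none"  # none | homogeneous | heterogeneous
    wgd_by_region: dict = field(default_factory=dict)
    clinical_group: str = ""
    gleason: int | None = None
    immune: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_ubiquitous + self.n_shared + self.n_private

    @property
    def non_ubiquitous_fraction(self) -> float:
        total = self.n_total
        return (self.n_shared + self.n_private) / total if total else float("nan")


@dataclass
class GroupComparison:
    """Mann–Whitney U comparison of one metric between two clinical groups."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact-enumeration" | "exact" | "asymptotic"
    group_labels: tuple[str, str] = ("", "")
    means: tuple[float, float] = (float("nan"), float("nan"))


# -- presence classification ---------------------------------------------------


def is_present(alt_count: int, ref_count: int) -> bool:
    """Presence rule: >= MIN_ALT_READS alt reads and VAF >= MIN_VAF."""
    depth = alt_count + ref_count
    if depth <= 0 or alt_count < MIN_ALT_READS:
        return False
    return alt_count / depth >= MIN_VAF


def _min_alt_needed(depth: int) -> int:
    return max(MIN_ALT_READS, math.ceil(MIN_VAF * depth))


def is_assessable(
    depth: int,
    expected_clonal_vaf: float,
    power_threshold: float = POWER_THRESHOLD,
) -> bool:
    """Would a clonal mutation at this site be detected with high probability?

    Detection power is the binomial probability of drawing at least the
    number of alt reads the presence rule requires, at the expected clonal
    VAF. Regions below the power threshold cannot count as true absences.
    """
    if depth <= 0:
        return False
    k = _min_alt_needed(depth)
    power = stats.binom.sf(k - 1, depth, expected_clonal_vaf)
    return bool(power >= power_threshold)


def classify_presence(
    present_by_region: dict[str, bool],
    assessable_by_region: dict[str, bool],
) -> str:
    """Classify one mutation as ubiquitous, shared or private.

    Regions where the mutation is observed always count; regions where it is
    absent count against ubiquity only if they are assessable (sufficient
    detection power). Raises on a mutation present in zero regions.
    """
    considered = [
        r
        for r in present_by_region
        if present_by_region[r] or assessable_by_region.get(r, False)
    ]
    n_present = sum(present_by_region[r] for r in considered)
    if n_present == 0:
        raise ValueError("mutation present in no region cannot be classified")
    if n_present == len(considered):
        return "ubiquitous"
    if n_present == 1:
        return "private"
    return "shared"


def classify_presence_table(
    variants: pd.DataFrame,
    purities: dict[str, float],
    *,
    multiplicity: int = 1,
    cn_total: int = 2,
    power_threshold: float = POWER_THRESHOLD,
) -> pd.DataFrame:
    """Presence class for every mutation of one patient.

    ``variants`` holds all per-region rows for one patient (rows with zero
    alt reads included where the site was assayed). The expected clonal VAF
    used in the power rule is ``rho * m / (rho*CN_t + 2(1-rho))`` with the
    supplied default multiplicity and copy number; region rows missing for a
    mutation are treated as unassessable (no data).

    Returns one row per mutation: key columns plus ``presence_class`` and
    ``n_regions_present``. Assayed sites where the presence rule fires in no
    region are not somatic calls at all and are silently dropped (the
    single-mutation classifier raises on them instead).
    """
    from .ccf_clustering import expected_vaf

    key_cols = ["chrom", "pos", "ref", "alt"]
    out_rows = []
    for key, grp in variants.groupby(key_cols, sort=False):
        present = {}
        assessable = {}
        for _, row in grp.iterrows():
            rid = row["region_id"]
            depth = int(row["alt_count"]) + int(row["ref_count"])
            present[rid] = is_present(int(row["alt_count"]), int(row["ref_count"]))
            ev = expected_vaf(1.0, purities[rid], cn_total, multiplicity)
            assessable[rid] = is_assessable(depth, ev, power_threshold)
        if not any(present.values()):
            continue
        cls = classify_presence(present, assessable)
        rec = dict(zip(key_cols, key))
        rec["gene"] = grp["gene"].iloc[0]
        rec["effect"] = grp["effect"].iloc[0]
        rec["context"] = grp["context"].iloc[0]
        rec["presence_class"] = cls
        rec["n_regions_present"] = int(sum(present.values()))
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def snv_burden(n_exonic_snvs: int, target_mb: float) -> float:
    """Exonic mutation burden: distinct SNVs in the patient union per Mb."""
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    return n_exonic_snvs / target_mb


# -- interval machinery for SCNA metrics --------------------------------------


def _merge_halfopen(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e > s]


def _total_len(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge_halfopen(intervals))


def _segments_halfopen(segments: pd.DataFrame) -> pd.DataFrame:
    seg = segments.copy()
    seg["start0"] = seg["start"] - 1
    seg["end0"] = seg["end"]
    seg["total_cn"] = seg["major_cn"] + seg["minor_cn"]
    return seg


def compute_fga(
    segments: pd.DataFrame,
    genome_length: int,
    *,
    wgd_by_region: dict[str, bool] | None = None,
) -> float:
    """Fraction of genome altered in *any* region of one patient.

    A base is altered when its total copy number differs from the neutral
    baseline — 2, or 4 in regions called whole-genome doubled. The union of
    altered bases across all regions is divided by the assessable genome
    length (configured autosome total by default; sex chromosomes are
    excluded from the denominator upstream).
    """
    if len(segments) == 0:
        raise ValueError("empty segment set: cannot distinguish neutral from missing")
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    wgd_by_region = wgd_by_region or {}
    seg = _segments_halfopen(segments)
    altered: dict[str, list[tuple[int, int]]] = {}
    for _, row in seg.iterrows():
        baseline = WGD_NEUTRAL_CN if wgd_by_region.get(row["region_id"]) else NEUTRAL_CN
        if row["total_cn"] != baseline:
            altered.setdefault(row["chrom"], []).append((row["start0"], row["end0"]))
    total = sum(_total_len(ivs) for ivs in altered.values())
    return total / genome_length


def scna_heterogeneous_fraction(
    segments: pd.DataFrame,
    *,
    wgd_by_region: dict[str, bool] | None = None,
) -> float:
    """Of the bases altered in any region, the fraction not altered in the
    same direction (gain vs loss) in *all* regions.

    Works on the breakpoint union: every (chrom, position) atom gets one
    state per region in {-1, 0, +1} relative to that region's neutral
    baseline; uncovered atoms are neutral. With a single region the quantity
    is undefined (returns NaN with a warning).
    """
    regions = sorted(segments["region_id"].unique())
    if len(regions) < 2:
        warnings.warn(
            "heterogeneous SCNA fraction undefined with < 2 regions",
            RuntimeWarning,
        )
        return float("nan")
    wgd_by_region = wgd_by_region or {}
    seg = _segments_halfopen(segments)
    altered_any = 0
    homogeneous = 0
    for chrom, cseg in seg.groupby("chrom", sort=False):
        cuts = sorted(set(cseg["start0"]) | set(cseg["end0"]))
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            states = []
            for rid in regions:
                rows = cseg[
                    (cseg["region_id"] == rid)
                    & (cseg["start0"] <= lo)
                    & (cseg["end0"] >= hi)
                ]
                baseline = WGD_NEUTRAL_CN if wgd_by_region.get(rid) else NEUTRAL_CN
                if len(rows):
                    states.append(int(np.sign(rows["total_cn"].iloc[0] - baseline)))
                else:
                    states.append(0)
            if any(s != 0 for s in states):
                altered_any += hi - lo
                if all(s == states[0] for s in states) and states[0] != 0:
                    homogeneous += hi - lo
    if altered_any == 0:
        return 0.0
    return (altered_any - homogeneous) / altered_any


def call_wgd(segments: pd.DataFrame) -> tuple[dict[str, bool], str]:
    """Whole-genome doubling per region, plus the patient-level flag.

    A region is WGD when more than half of its covered bases have major
    allele copy number >= 2. Patient flag: ``homogeneous`` (all regions),
    ``heterogeneous`` (some), ``none``.
    """
    seg = _segments_halfopen(segments)
    by_region: dict[str, bool] = {}
    for rid, rseg in seg.groupby("region_id", sort=False):
        lengths = (rseg["end0"] - rseg["start0"]).to_numpy(dtype=float)
        covered = lengths.sum()
        doubled = lengths[(rseg["major_cn"] >= 2).to_numpy()].sum()
        by_region[rid] = bool(covered > 0 and doubled / covered > WGD_MAJOR_FRACTION)
    flags = list(by_region.values())
    if all(flags) and flags:
        patient = "homogeneous"
    elif any(flags):
        patient = "heterogeneous"
    else:
        patient = "none"
    return by_region, patient


# -- cohort statistics ---------------------------------------------------------


def correlate_ith(
    non_ubiquitous_fraction: np.ndarray, heterogeneous_scna_fraction: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between SNV and SCNA heterogeneity across patients."""
    x = np.asarray(non_ubiquitous_fraction, dtype=float)
    y = np.asarray(heterogeneous_scna_fraction, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 patients with both heterogeneity metrics")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a heterogeneity metric: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U for sample x (ties counted half)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_enumeration_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all group assignments (handles ties).

    U is computed from midranks (sum of group-1 ranks minus n1(n1+1)/2),
    which equals the pairwise greater-than count with ties counted half;
    enumeration over all C(n, n1) assignments is vectorised.
    """
    combined = np.concatenate([x, y])
    n1 = len(x)
    n = len(combined)
    ranks = stats.rankdata(combined)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    combos = np.array(list(itertools.combinations(range(n), n1)))
    us = ranks[combos].sum(axis=1) - offset
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return u_obs, float(p)


def compare_groups(
    values1,
    values2,
    *,
    method: str = "auto",
    labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Two-sided Mann–Whitney U test between two clinical groups.

    Method selection (``auto``): tie-free data uses the exact Mann–Whitney
    distribution; tied data with ``min(n1, n2) <= 8`` uses full enumeration
    of all rank assignments (exact under ties); larger tied samples fall
    back to the normal approximation with tie correction. All-tied input
    yields p = 1 with a warning. ``method`` may force any of
    ``exact-enumeration``, ``exact``, ``asymptotic``.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all values tied across groups; p = 1", RuntimeWarning)
        return GroupComparison(
            u_statistic=len(x) * len(y) / 2.0,
            p_value=1.0,
            n1=len(x),
            n2=len(y),
            method="degenerate",
            group_labels=labels,
            means=(float(x.mean()), float(y.mean())),
        )
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if method == "auto":
        if not has_ties:
            method = "exact"
        elif min(len(x), len(y)) <= 8:
            method = "exact-enumeration"
        else:
            method = "asymptotic"
    if method == "exact-enumeration":
        u, p = _exact_enumeration_p(x, y)
    elif method == "exact":
        if has_ties:
            raise ValueError("exact distribution path requires tie-free data")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        u, p = float(res.statistic), float(res.pvalue)
    elif method == "asymptotic":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        u_statistic=u,
        p_value=p,
        n1=len(x),
        n2=len(y),
        method=method,
        group_labels=labels,
        means=(float(x.mean()), float(y.mean())),
    )
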