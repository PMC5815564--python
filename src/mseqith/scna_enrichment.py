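"""Recurrent locus-level SCNA calling and group enrichment testing.

A locus (focal peak or chromosome arm, supplied as a catalogue of 1-based
inclusive intervals) is called per region when at least half of it is
gained (total CN above neutral) or lost (below neutral); per-patient status
is ``ubiquitous`` (event in every region), ``heterogeneous`` (some regions)
or ``absent``. Group enrichment is a two-sided Fisher exact test on the
collapsed present/absent table.

Because patients differ in genome-wide SCNA burden, a locus can look
enriched in the high-burden group for burden reasons alone. The
burden-controlled test therefore builds a "spinning" null: each permutation
re-places every observed altered segment of each patient uniformly at
random on the genome (lengths and per-region segment counts preserved),
re-calls the locus and recomputes the between-group difference in locus
frequency. This conditions exactly on each patient's altered-base burden
and segment-length spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heterogeneity import NEUTRAL_CN, _merge_halfopen

__all__ = [
    "Locus",
    "LocusEvent",
    "DEFAULT_LOCI",
    "call_locus_event",
    "enrichment_test",
    "burden_controlled_enrichment",
    "read_locus_catalogue",
]

#: Minimum fraction of the locus that must be covered by the event.
LOCUS_OVERLAP_THRESHOLD = 0.5


@dataclass(frozen=True)
class Locus:
    """A catalogue entry; coordinates 1-based inclusive as on disk."""

    locus_id: str
    chrom: str
    start: int
    end: int
    direction: str  # "gain" | "loss"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LocusEvent:
    locus: Locus
    patient_id: str
    status: str  # "ubiquitous" | "heterogeneous" | "absent"
    regions_with_event: list


#: Catalogue of recurrent prostate-cancer SCNA loci shipped as defaults
#: (GRCh37 approximate cytoband coordinates); user catalogues override.
DEFAULT_LOCI = [
    Locus("3q21.3", "3", 125_800_001, 129_200_000, "gain"),
    Locus("3q26.2", "3", 168_600_001, 170_900_000, "gain"),
    Locus("8q", "8", 45_600_001, 146_364_022, "gain"),
    Locus("7p", "7", 1, 60_100_000, "gain"),
    Locus("8p21", "8", 19_000_001, 23_300_000, "loss"),
]


def read_locus_catalogue(path) -> list[Locus]:
    """Read a BED-like TSV catalogue (columns: locus_id, chrom, start, end,
    direction; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["locus_id", "chrom", "start", "end", "direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"locus catalogue missing column(s): {missing}")
    loci = []
    for _, row in df.iterrows():
        if row["direction"] not in {"gain", "loss"}:
            raise ValueError(f"locus {row['locus_id']}: bad direction {row['direction']!r}")
        loci.append(
            Locus(row["locus_id"], row["chrom"], int(row["start"]), int(row["end"]), row["direction"])
        )
    return loci


def _locus_covered_fraction(
    segments: pd.DataFrame, locus: Locus, direction: str, neutral: int
) -> float:
    """Fraction of the locus covered by segments altered in ``direction``
    (union over segments) for one region's segment table."""
    lo0, hi0 = locus.start - 1, locus.end
    seg = segments[segments["chrom"] == locus.chrom]
    total = seg["major_cn"] + seg["minor_cn"]
    if direction == "gain":
        seg = seg[total > neutral]
    else:
        seg = seg[total < neutral]
    ivs = []
    for _, row in seg.iterrows():
        s = max(int(row["start"]) - 1, lo0)
        e = min(int(row["end"]), hi0)
        if e > s:
            ivs.append((s, e))
    covered = sum(e - s for s, e in _merge_halfopen(ivs))
    return covered / (hi0 - lo0)


def call_locus_event(
    segments: pd.DataFrame,
    locus: Locus,
    *,
    direction: str | None = None,
    neutral: int = NEUTRAL_CN,
    overlap_threshold: float = LOCUS_OVERLAP_THRESHOLD,
    genome: dict[str, int] | None = None,
) -> LocusEvent:
    """Per-patient status of one locus from one patient's multi-region segments.

    A region carries the event when the gained (or lost) bases cover at
    least ``overlap_threshold`` of the locus. Status: event in all regions
    -> ubiquitous; in some -> heterogeneous; in none -> absent.
    """
    direction = direction or locus.direction
    if genome is not None:
        length = genome.get(locus.chrom)
        if length is None or locus.end > length or locus.start < 1:
            raise ValueError(
                f"locus {locus.locus_id} ({locus.chrom}:{locus.start}-{locus.end}) "
                "lies outside the configured genome"
            )
    patient_id = segments["patient_id"].iloc[0] if len(segments) else ""
    regions = sorted(segments["region_id"].unique())
    hit = []
    for rid in regions:
        frac = _locus_covered_fraction(
            segments[segments["region_id"] == rid], locus, direction, neutral
        )
        if frac >= overlap_threshold:
            hit.append(rid)
    if regions and len(hit) == len(regions):
        status = "ubiquitous"
    elif hit:
        status = "heterogeneous"
    else:
        status = "absent"
    return LocusEvent(locus=locus, patient_id=patient_id, status=status, regions_with_event=hit)


def enrichment_test(
    status_by_patient: dict[str, str],
    group_by_patient: dict[str, str],
    *,
    groups: tuple[str, str] = ("mHNPC", "hrlPC"),
) -> tuple[float, float, list[list[int]]]:
    """Fisher exact two-sided test of locus presence between clinical groups.

    Status is collapsed to present (ubiquitous or heterogeneous) vs absent.
    Returns (odds_ratio, p, table) with table rows = groups, columns =
    (present, absent).
    """
    table = [[0, 0], [0, 0]]
    for pid, status in status_by_patient.items():
        g = group_by_patient[pid]
        if g not in groups:
            continue
        i = groups.index(g)
        j = 0 if status in {"ubiquitous", "heterogeneous"} else 1
        table[i][j] += 1
    if sum(table[0]) == 0 or sum(table[1]) == 0:
        raise ValueError("both clinical groups must be non-empty")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


# -- burden-controlled permutation test ---------------------------------------


def _altered_segment_lengths(
    segments: pd.DataFrame, direction: str, neutral: int
) -> dict[str, list[int]]:
    """Per-region lengths (bases) of segments altered in the tested direction."""
    total = segments["major_cn"] + segments["minor_cn"]
    if direction == "gain":
        seg = segments[total > neutral]
    else:
        seg = segments[total < neutral]
    out: dict[str, list[int]] = {}
    for rid, rseg in seg.groupby("region_id", sort=False):
        out[rid] = (rseg["end"] - rseg["start"] + 1).astype(int).tolist()
    return out


def _region_hits_locus(
    starts: np.ndarray, lengths: np.ndarray, lo0: int, hi0: int, threshold_bases: float
) -> bool:
    """Does the union of placed segments cover >= threshold_bases of the locus?"""
    s = np.maximum(starts, lo0)
    e = np.minimum(starts + lengths, hi0)
    ov = e - s
    idx = np.nonzero(ov > 0)[0]
    if len(idx) == 0:
        return False
    if len(idx) == 1:
        return ov[idx[0]] >= threshold_bases
    covered = sum(ee - ss for ss, ee in _merge_halfopen([(int(s[i]), int(e[i])) for i in idx]))
    return covered >= threshold_bases


def burden_controlled_enrichment(
    segments_by_patient: dict[str, pd.DataFrame],
    locus: Locus,
    group_by_patient: dict[str, str],
    genome: list[tuple[str, int]],
    *,
    direction: str | None = None,
    groups: tuple[str, str] = ("mHNPC", "hrlPC"),
    neutral: int = NEUTRAL_CN,
    overlap_threshold: float = LOCUS_OVERLAP_THRESHOLD,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test of locus enrichment conditioned on SCNA burden.

    Observed statistic: difference in locus-presence frequency between the
    two groups (first minus second). Null: per permutation, each patient's
    altered segments are re-placed uniformly on the genome (lengths and
    per-region counts preserved), the locus re-called and the statistic
    recomputed. p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    direction = direction or locus.direction
    rng = np.random.default_rng(seed)
    chrom_names = [c for c, _ in genome]
    chrom_lengths = np.array([l for _, l in genome], dtype=float)
    locus_ci = chrom_names.index(locus.chrom)
    lo0, hi0 = locus.start - 1, locus.end
    threshold_bases = overlap_threshold * (hi0 - lo0)

    members = {g: [p for p, gg in group_by_patient.items() if gg == g] for g in groups}
    if not members[groups[0]] or not members[groups[1]]:
        raise ValueError("both clinical groups must be non-empty")

    def observed_present(pid: str) -> bool:
        ev = call_locus_event(
            segments_by_patient[pid],
            locus,
            direction=direction,
            neutral=neutral,
            overlap_threshold=overlap_threshold,
        )
        return ev.status != "absent"

    def freq_diff(present: dict[str, bool]) -> float:
        f = [
            np.mean([present[p] for p in members[g]]) if members[g] else 0.0
            for g in groups
        ]
        return float(f[0] - f[1])

    obs_present = {pid: observed_present(pid) for pid in group_by_patient}
    observed = freq_diff(obs_present)

    # pre-extract altered segment lengths per patient/region
    lengths_by_patient = {
        pid: _altered_segment_lengths(segments_by_patient[pid], direction, neutral)
        for pid in group_by_patient
    }

    null = np.empty(n_perm)
    for b in range(n_perm):
        present = {}
        for pid, by_region in lengths_by_patient.items():
            hit_any = False
            for _rid, lens in by_region.items():
                if hit_any or not lens:
                    continue
                lens_arr = np.array(lens, dtype=float)
                # choose a chromosome able to hold each segment, with
                # probability proportional to the number of valid start
                # positions, then a uniform valid start on it
                slack = np.maximum(chrom_lengths[None, :] - lens_arr[:, None], 0.0)
                cum = slack.cumsum(axis=1)
                u = rng.random(len(lens)) * cum[:, -1]
                chroms = (cum > u[:, None]).argmax(axis=1)
                starts = rng.uniform(0, slack[np.arange(len(lens)), chroms])
                on_locus = chroms == locus_ci
                if on_locus.any() and _region_hits_locus(
                    starts[on_locus], lens_arr[on_locus], lo0, hi0, threshold_bases
                ):
                    hit_any = True
            present[pid] = hit_any
        null[b] = freq_diff(present)

    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_perm)
    return {
        "observed_diff": observed,
        "p_value": float(p),
        "n_perm": n_perm,
        "null_mean": float(null.mean()),
        "observed_present": obs_present,
    }
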