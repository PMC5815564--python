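"""Synthetic multi-region cohort generator with full ground truth.

Emulates a prospective multi-region prostate-biopsy sequencing cohort: 25
patients, 2–4 tumour regions each, clone trees of 2–6 clones with
region-specific clone mixtures, binomial read sampling at configurable
depth and purity, allele-specific copy-number segments with truncal and
region-private events, signature-structured trinucleotide contexts, and
per-region immune counts whose link to genomic covariates (mismatch-repair
deficiency, Wnt-pathway activation) is configurable. Every stochastic
choice is recorded in a truth bundle so each inference stage downstream can
be validated by parameter recovery.

Generative model highlights:

* Clone CCFs are assigned by stick-breaking down the tree independently
  per region, so the sibling-sum (pigeonhole) rule holds exactly by
  construction; the trunk has CCF 1 everywhere.
* Expected VAF of a mutation in clone ``c``, region ``r`` is
  ``rho_r * CCF(r, c) * m / (rho_r * CN_t + 2 * (1 - rho_r))``; alt reads
  are binomial at a Poisson-drawn depth (floored at 1).
* Segment tables fully partition each chromosome (background at the
  region's neutral baseline), so validation, WGD calling and FGA work
  without missing-data conventions. Truncal SCNAs sit on the trunk clone;
  region-private SCNAs on non-trunk clones.
* The per-patient altered-genome fraction is drawn from a truncated normal
  around the clinical group's configured mean, so group contrasts in FGA
  are known by construction.
* Immune model: INIF is Beta-distributed with mean shifts for MMRD and Wnt
  flags; the patient CD8+/FOXP3+ ratio is log-normal with a lower mean for
  Wnt-activated patients; per-region counts are Poisson around the patient
  ratio. Neoantigen burdens are derived from mutation counts independently
  of INIF.

All randomness flows from a single integer seed through spawned
``numpy.random`` substreams, so cohorts are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import SampleSheet, SegmentLookup
from .signatures import CONTEXT_KEYS, builtin_catalogue, parse_context

__all__ = [
    "DEFAULT_GENOME",
    "CloneTreeTruth",
    "SimulationConfig",
    "PatientBundle",
    "CohortBundle",
    "simulate_clone_tree",
    "simulate_patient",
    "simulate_cohort",
]

#: Synthetic autosome set (name, length in bp); approximately the GRCh37
#: autosome lengths at megabase precision. Sex chromosomes are excluded
#: (male-cohort hemizygosity complicates the neutral state), so this sum is
#: also the default FGA denominator.
DEFAULT_GENOME: list[tuple[str, int]] = [
    ("1", 249_000_000), ("2", 243_000_000), ("3", 198_000_000),
    ("4", 191_000_000), ("5", 181_000_000), ("6", 171_000_000),
    ("7", 159_000_000), ("8", 146_000_000), ("9", 141_000_000),
    ("10", 136_000_000), ("11", 135_000_000), ("12", 134_000_000),
    ("13", 115_000_000), ("14", 107_000_000), ("15", 103_000_000),
    ("16", 90_000_000), ("17", 81_000_000), ("18", 78_000_000),
    ("19", 59_000_000), ("20", 63_000_000), ("21", 48_000_000),
    ("22", 51_000_000),
]

_EFFECTS = ["missense", "silent", "nonsense", "other"]
_EFFECT_PROBS = [0.60, 0.25, 0.10, 0.05]

_WNT_GOF = ["p.S33P", "p.S33C", "p.T41A"]
_CTNNB1_POS = ("3", 41_266_000)
_MSH2_DEL = ("2", 47_000_000, 48_100_000)  # spans MSH2 and MSH6
_MSH6_VARIANT_POS = ("2", 48_020_000)


@dataclass
class CloneTreeTruth:
    """Ground-truth clonal structure of one simulated patient."""

    patient_id: str
    nodes: list[int]
    parent: dict[int, int | None]
    clone_ccf: dict[tuple[str, int], float]  # (region_id, clone) -> CCF
    mutation_assignment: dict[str, int] = field(default_factory=dict)
    signature_weights_by_clone: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def root(self) -> int:
        return next(n for n, p in self.parent.items() if p is None)

    def regions(self) -> list[str]:
        return sorted({r for r, _ in self.clone_ccf})

    def children(self, node: int) -> list[int]:
        return [n for n, p in self.parent.items() if p == node]

    def check_sum_rule(self, tol: float = 1e-9) -> None:
        """Assert trunk CCF 1 and the sibling-sum rule in every region."""
        for r in self.regions():
            if abs(self.clone_ccf[(r, self.root)] - 1.0) > tol:
                raise AssertionError(f"trunk CCF != 1 in region {r}")
            for node in self.nodes:
                kids = self.children(node)
                if not kids:
                    continue
                s = sum(self.clone_ccf[(r, k)] for k in kids)
                if s > self.clone_ccf[(r, node)] + tol:
                    raise AssertionError(
                        f"sibling-sum rule violated at node {node}, region {r}"
                    )


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_patients: int = 25
    frac_metastatic: float = 12 / 25
    regions_per_patient: tuple[int, int] = (2, 4)
    clones_per_patient: tuple[int, int] = (2, 6)
    depth: float = 100.0
    purity_range: tuple[float, float] = (0.4, 0.8)
    mutations_per_clone: tuple[int, int] = (5, 30)
    genome: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_GENOME))
    target_mb: float = 30.0  # exome footprint for burden per Mb
    # SCNA model
    fga_mean: dict[str, float] = field(
        default_factory=lambda: {"mHNPC": 0.30, "hrlPC": 0.12}
    )
    fga_sd: float = 0.08
    fga_bounds: tuple[float, float] = (0.02, 0.45)
    gain_fraction: float = 0.5  # share of altered bases that are gains
    truncal_scna_fraction: float = 0.5
    segment_length_mb: tuple[float, float] = (10.0, 80.0)  # log-uniform range
    clone_cn_presence_threshold: float = 0.25
    wgd_prob: float = 0.15
    # mutation model
    signature_catalogue: pd.DataFrame | None = None
    trunk_signature_weights: dict[str, float] = field(
        default_factory=lambda: {"clock_like": 0.7, "flat": 0.3}
    )
    branch_signature_weights: dict[str, float] = field(
        default_factory=lambda: {"clock_like": 0.3, "flat": 0.5, "mmrd_like": 0.2}
    )
    purine_strand_prob: float = 0.5  # fraction of contexts emitted unfolded
    high_multiplicity_prob: float = 0.1  # truncal mutations on gains with m = major
    # genotype flags
    wnt_prob: float = 0.3
    mmrd_prob: float = 0.08
    hypermutation_factor: float = 12.0
    mmrd_trunk_signature_weights: dict[str, float] = field(
        default_factory=lambda: {"mmrd_like": 0.4, "clock_like": 0.4, "flat": 0.2}
    )
    # immune model
    inif_mean: float = 8.0  # percent, baseline
    inif_concentration: float = 8.0
    inif_mmrd_mean: float = 30.0
    inif_wnt_mean: float = 12.0
    ratio_mean_wt: float = 6.08
    ratio_mean_wnt: float = 2.65
    ratio_sigma_wt: float = 0.73  # log-scale sd reproducing ~6.08 +/- 5.0
    ratio_sigma_wnt: float = 0.43  # log-scale sd reproducing ~2.65 +/- 1.2
    foxp3_base_count: float = 20.0
    neoantigen_rate: float = 0.8  # binders per non-silent mutation
    clonal_neoantigen_fraction: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must lie in (0, 1]")
        cat = self.catalogue()
        if (cat.to_numpy() < 0).any():
            raise ValueError("signature catalogue has negative probabilities")
        if not np.allclose(cat.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("each signature's 96 context probabilities must sum to 1")

    def catalogue(self) -> pd.DataFrame:
        return (
            self.signature_catalogue
            if self.signature_catalogue is not None
            else builtin_catalogue()
        )

    def genome_length(self) -> int:
        return sum(l for _, l in self.genome)


@dataclass
class PatientBundle:
    patient_id: str
    group: str
    variants: pd.DataFrame
    segments: pd.DataFrame
    purity: dict[str, float]
    immune: dict[str, dict[str, float]]
    truth: CloneTreeTruth
    flags: dict = field(default_factory=dict)


@dataclass
class CohortBundle:
    config: SimulationConfig
    patients: list[PatientBundle]

    @property
    def variants(self) -> pd.DataFrame:
        frames = [p.variants for p in self.patients]
        return pd.concat(frames, ignore_index=True) if frames else _empty_variants()

    @property
    def segments(self) -> pd.DataFrame:
        frames = [p.segments for p in self.patients]
        return pd.concat(frames, ignore_index=True) if frames else _empty_segments()

    def sheet(self) -> SampleSheet:
        patients = {}
        for p in self.patients:
            regions = {}
            for rid in sorted(p.purity):
                rec = {"purity": round(float(p.purity[rid]), 4)}
                rec.update({k: v for k, v in p.immune[rid].items()})
                regions[rid] = rec
            patients[p.patient_id] = {
                "group": p.group,
                "gleason": p.flags.get("gleason", 7),
                "neoantigen_burden": p.flags.get("neoantigen_burden"),
                "clonal_neoantigen_burden": p.flags.get("clonal_neoantigen_burden"),
                "regions": regions,
            }
        return SampleSheet(patients=patients)

    def truth_dict(self) -> dict:
        out = {}
        for p in self.patients:
            out[p.patient_id] = {
                "group": p.group,
                "nodes": p.truth.nodes,
                "parent": {str(k): v for k, v in p.truth.parent.items()},
                "clone_ccf": {
                    f"{r}:{c}": round(v, 6) for (r, c), v in p.truth.clone_ccf.items()
                },
                "mutation_assignment": p.truth.mutation_assignment,
                "signature_weights_by_clone": {
                    str(k): v for k, v in p.truth.signature_weights_by_clone.items()
                },
                "flags": {
                    k: v for k, v in p.flags.items() if not isinstance(v, pd.DataFrame)
                },
            }
        return out


def _empty_variants() -> pd.DataFrame:
    from .io_formats import VARIANT_COLUMNS

    return pd.DataFrame(columns=VARIANT_COLUMNS + ["protein_change", "mutation_id"])


def _empty_segments() -> pd.DataFrame:
    from .io_formats import SEGMENT_COLUMNS

    return pd.DataFrame(columns=SEGMENT_COLUMNS)


# -- clone trees ---------------------------------------------------------------


def simulate_clone_tree(
    n_clones: int,
    seed: int,
    *,
    n_regions: int = 3,
    region_ids: list[str] | None = None,
    patient_id: str = "",
    absent_prob: float = 0.35,
) -> CloneTreeTruth:
    """Random rooted clone tree with stick-broken per-region CCFs.

    Topology: clone ``i`` picks its parent uniformly among clones ``0..i-1``
    (clone 0 is the trunk). CCFs: per region, each node's children receive
    Dirichlet-distributed shares of the parent's CCF (one extra share stays
    with the parent), and each non-trunk clone is zeroed in a region with
    probability ``absent_prob`` — producing region-specific clone mixtures.
    The sibling-sum rule holds exactly by construction; the trunk has CCF 1
    in every region.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    region_ids = region_ids or [f"R{i + 1}" for i in range(n_regions)]
    nodes = list(range(n_clones))
    parent: dict[int, int | None] = {0: None}
    for i in range(1, n_clones):
        parent[i] = int(rng.integers(0, i))
    children: dict[int, list[int]] = {n: [] for n in nodes}
    for n, p in parent.items():
        if p is not None:
            children[p].append(n)

    # each clone gets a home region where the dropout mask never applies, so
    # every clone is observable somewhere (conditional on its parent being
    # present there, which holds along home-region chains by construction)
    home = {k: region_ids[int(rng.integers(0, len(region_ids)))] for k in nodes}
    clone_ccf: dict[tuple[str, int], float] = {}
    for r in region_ids:
        clone_ccf[(r, 0)] = 1.0
        # BFS so parents are assigned before children
        queue = [0]
        while queue:
            node = queue.pop(0)
            kids = children[node]
            if not kids:
                continue
            shares = rng.dirichlet(np.ones(len(kids) + 1))[:-1]
            present = rng.random(len(kids)) >= absent_prob
            for k, s, keep in zip(kids, shares, present):
                keep = keep or r == home[k]
                clone_ccf[(r, k)] = float(clone_ccf[(r, node)] * s * keep)
                queue.append(k)
    # a clone whose ancestors dropped out of its home region can still be
    # absent everywhere; re-anchor such clones under their parent's best region
    for k in nodes[1:]:
        if all(clone_ccf[(r, k)] == 0.0 for r in region_ids):
            best = max(
                region_ids,
                key=lambda r: clone_ccf[(r, parent[k])]
                - sum(clone_ccf[(r, s)] for s in children[parent[k]] if s != k),
            )
            headroom = clone_ccf[(best, parent[k])] - sum(
                clone_ccf[(best, s)] for s in children[parent[k]] if s != k
            )
            clone_ccf[(best, k)] = float(max(headroom, 0.0) * rng.uniform(0.3, 0.9))

    truth = CloneTreeTruth(
        patient_id=patient_id, nodes=nodes, parent=parent, clone_ccf=clone_ccf
    )
    truth.check_sum_rule()
    return truth


# -- segments ------------------------------------------------------------------


def _place_segments(
    rng: np.random.Generator,
    genome: list[tuple[str, int]],
    target_bases: float,
    length_range_mb: tuple[float, float],
    occupied: dict[str, list[tuple[int, int]]],
) -> list[tuple[str, int, int]]:
    """Place non-overlapping intervals totalling ~target_bases; half-open 0-based."""
    chrom_names = [c for c, _ in genome]
    lengths = np.array([l for _, l in genome], dtype=float)
    probs = lengths / lengths.sum()
    placed: list[tuple[str, int, int]] = []
    remaining = target_bases
    lo_mb, hi_mb = length_range_mb
    attempts = 0
    while remaining > 0.25 * lo_mb * 1e6 and attempts < 500:
        attempts += 1
        seg_len = int(np.exp(rng.uniform(np.log(lo_mb * 1e6), np.log(hi_mb * 1e6))))
        seg_len = int(min(seg_len, max(remaining, lo_mb * 1e6)))
        ci = rng.choice(len(chrom_names), p=probs)
        chrom, clen = chrom_names[ci], int(lengths[ci])
        if seg_len >= clen:
            continue
        start = int(rng.integers(0, clen - seg_len))
        iv = (start, start + seg_len)
        if any(s < iv[1] and iv[0] < e for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append(iv)
        placed.append((chrom, iv[0], iv[1]))
        remaining -= seg_len
    return placed


def _build_segment_table(
    patient_id: str,
    region_ids: list[str],
    genome: list[tuple[str, int]],
    events: list[dict],
    wgd: bool,
) -> pd.DataFrame:
    """Full-coverage per-region segment table: events over a neutral background."""
    base_major, base_minor = (2, 2) if wgd else (1, 1)
    rows = []
    for rid in region_ids:
        for chrom, clen in genome:
            evs = sorted(
                (e for e in events if e["chrom"] == chrom and rid in e["regions"]),
                key=lambda e: e["start0"],
            )
            cursor = 0
            for e in evs:
                if e["start0"] > cursor:
                    rows.append(
                        (patient_id, rid, chrom, cursor + 1, e["start0"], base_major, base_minor)
                    )
                rows.append(
                    (patient_id, rid, chrom, e["start0"] + 1, e["end0"], e["major"], e["minor"])
                )
                cursor = e["end0"]
            if cursor < clen:
                rows.append((patient_id, rid, chrom, cursor + 1, clen, base_major, base_minor))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "region_id", "chrom", "start", "end", "major_cn", "minor_cn"],
    )


# -- patients ------------------------------------------------------------------


def _normalise_weights(weights: dict[str, float], names: list[str]) -> dict[str, float]:
    w = {k: float(v) for k, v in weights.items() if k in names}
    tot = sum(w.values())
    if tot <= 0:
        raise ValueError("signature weights must have positive total")
    return {k: v / tot for k, v in w.items()}


def _sample_context(
    rng: np.random.Generator,
    catalogue: pd.DataFrame,
    weights: dict[str, float],
    purine_prob: float,
) -> str:
    names = list(weights)
    probs = np.array([weights[n] for n in names])
    sig = names[int(rng.choice(len(names), p=probs))]
    col = catalogue[sig].to_numpy()
    key = CONTEXT_KEYS[int(rng.choice(96, p=col / col.sum()))]
    if rng.random() < purine_prob:
        # emit on the purine strand; count_contexts folds it back
        ref, alt, five, three = parse_context(key)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        key = f"{comp[three]}[{comp[ref]}>{comp[alt]}]{comp[five]}"
    return key




def simulate_patient(
    config: SimulationConfig,
    seed: int,
    *,
    patient_id: str = "P001",
    group: str = "hrlPC",
    force_wnt: bool | None = None,
    force_mmrd: bool | None = None,
) -> PatientBundle:
    """Simulate one patient: variants, segments, purity, immune counts, truth."""
    config.validate()
    rng = np.random.default_rng(seed)
    catalogue = config.catalogue()
    sig_names = list(catalogue.columns)

    n_regions = int(rng.integers(config.regions_per_patient[0], config.regions_per_patient[1] + 1))
    n_clones = int(rng.integers(config.clones_per_patient[0], config.clones_per_patient[1] + 1))
    region_ids = [f"R{i + 1}" for i in range(n_regions)]
    truth = simulate_clone_tree(
        n_clones,
        int(rng.integers(0, 2**31 - 1)),
        region_ids=region_ids,
        patient_id=patient_id,
    )
    purity = {r: float(rng.uniform(*config.purity_range)) for r in region_ids}
    wgd = bool(rng.random() < config.wgd_prob)

    is_mmrd = bool(rng.random() < config.mmrd_prob) if force_mmrd is None else force_mmrd
    is_wnt = bool(rng.random() < config.wnt_prob) if force_wnt is None else force_wnt

    # --- copy-number events -------------------------------------------------
    from scipy.stats import truncnorm

    mu = config.fga_mean[group]
    a, b = (config.fga_bounds[0] - mu) / config.fga_sd, (config.fga_bounds[1] - mu) / config.fga_sd
    fga_target = float(truncnorm.rvs(a, b, loc=mu, scale=config.fga_sd, random_state=rng))
    target_bases = fga_target * config.genome_length()

    occupied: dict[str, list[tuple[int, int]]] = {}
    if is_mmrd:  # reserve the MMR-gene interval for the planted deletion
        occupied.setdefault(_MSH2_DEL[0], []).append(_MSH2_DEL[1:])
    gains = _place_segments(
        rng, config.genome, target_bases * config.gain_fraction,
        config.segment_length_mb, occupied,
    )
    losses = _place_segments(
        rng, config.genome, target_bases * (1.0 - config.gain_fraction),
        config.segment_length_mb, occupied,
    )

    # clones eligible to carry private SCNAs: detectable somewhere
    eligible_clones = [
        c for c in truth.nodes[1:]
        if max(truth.clone_ccf[(r, c)] for r in region_ids) >= config.clone_cn_presence_threshold
    ]
    events: list[dict] = []
    for direction, placed in (("gain", gains), ("loss", losses)):
        for chrom, s0, e0 in placed:
            truncal = (not eligible_clones) or (rng.random() < config.truncal_scna_fraction)
            if truncal:
                clone = truth.root
                regions = list(region_ids)
            else:
                clone = int(rng.choice(eligible_clones))
                regions = [
                    r for r in region_ids
                    if truth.clone_ccf[(r, clone)] >= config.clone_cn_presence_threshold
                ]
            if direction == "gain":
                major, minor = (3, 2) if wgd else (2, 1)
            else:
                major, minor = (2, 1) if wgd else (1, 0)
            events.append(
                {"chrom": chrom, "start0": s0, "end0": e0, "major": major,
                 "minor": minor, "direction": direction, "clone": clone,
                 "regions": regions}
            )
    if is_mmrd:
        # biallelic MMR inactivation: truncal deletion over the MSH2/MSH6
        # region plus (BP0001-like) a germline variant hit
        chrom, s, e = _MSH2_DEL
        events.append(
            {"chrom": chrom, "start0": s, "end0": e,
             "major": 2 if wgd else 1, "minor": 0,
             "direction": "loss", "clone": truth.root, "regions": list(region_ids)}
        )
    segments = _build_segment_table(patient_id, region_ids, config.genome, events, wgd)

    # --- mutations ----------------------------------------------------------
    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = np.array([l for _, l in config.genome], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()

    hyper = config.hypermutation_factor if is_mmrd else 1.0
    trunk_w = _normalise_weights(
        config.mmrd_trunk_signature_weights if is_mmrd else config.trunk_signature_weights,
        sig_names,
    )
    branch_w = _normalise_weights(config.branch_signature_weights, sig_names)
    truth.signature_weights_by_clone = {
        c: (trunk_w if c == truth.root else branch_w) for c in truth.nodes
    }

    mut_rows = []
    mut_meta = []  # (mutation_id, clone, chrom, pos, m_by_region)
    counter = 0
    for clone in truth.nodes:
        n_mut = int(
            rng.integers(config.mutations_per_clone[0], config.mutations_per_clone[1] + 1)
            * hyper
        )
        weights = truth.signature_weights_by_clone[clone]
        for _ in range(n_mut):
            ci = int(rng.choice(len(chrom_names), p=chrom_probs))
            chrom = chrom_names[ci]
            pos = int(rng.integers(1, int(chrom_lengths[ci])))
            key = _sample_context(rng, catalogue, weights, config.purine_strand_prob)
            ref, alt, _, _ = parse_context(key)
            counter += 1
            mid = f"{patient_id}_M{counter:05d}"
            effect = _EFFECTS[int(rng.choice(len(_EFFECTS), p=_EFFECT_PROBS))]
            gene = f"GENE{int(rng.integers(1, 400)):03d}"
            mut_meta.append(
                {"mutation_id": mid, "clone": clone, "chrom": chrom, "pos": pos,
                 "ref": ref, "alt": alt, "gene": gene, "effect": effect,
                 "context": key, "germline": False, "protein_change": ""}
            )
    # planted driver events
    if is_wnt:
        counter += 1
        pc = _WNT_GOF[int(rng.integers(0, len(_WNT_GOF)))]
        clone = int(rng.choice(truth.nodes))
        mut_meta.append(
            {"mutation_id": f"{patient_id}_M{counter:05d}", "clone": clone,
             "chrom": _CTNNB1_POS[0], "pos": _CTNNB1_POS[1] + int(rng.integers(0, 1000)),
             "ref": "C", "alt": "T", "gene": "CTNNB1", "effect": "missense",
             "context": "A[C>T]G", "germline": False, "protein_change": pc}
        )
    if is_mmrd:
        counter += 1
        mut_meta.append(
            {"mutation_id": f"{patient_id}_M{counter:05d}", "clone": truth.root,
             "chrom": _MSH6_VARIANT_POS[0], "pos": _MSH6_VARIANT_POS[1],
             "ref": "C", "alt": "T", "gene": "MSH6", "effect": "missense",
             "context": "G[C>T]A", "germline": True, "protein_change": "p.G39E"}
        )

    cn_lookup = SegmentLookup(segments)
    for meta in mut_meta:
        truth.mutation_assignment[meta["mutation_id"]] = meta["clone"]
        clone = meta["clone"]
        # multiplicity: occasionally mutant allele on every copy of a gain
        m_high = clone == truth.root and rng.random() < config.high_multiplicity_prob
        for rid in region_ids:
            cn_total, cn_major = cn_lookup.at(rid, meta["chrom"], meta["pos"])
            rho = purity[rid]
            ccf = truth.clone_ccf[(rid, clone)]
            if cn_total == 0:
                vaf_exp, m = 0.0, 0
            else:
                m = cn_major if m_high else 1
                vaf_exp = ccf * rho * m / (rho * cn_total + 2.0 * (1.0 - rho))
            if vaf_exp > 1.0 + 1e-9:
                raise AssertionError(
                    f"expected VAF {vaf_exp:.3f} > 1 at {meta['mutation_id']}/{rid}; "
                    "generator invariant violated"
                )
            depth = max(1, int(rng.poisson(config.depth)))
            alt_reads = int(rng.binomial(depth, min(vaf_exp, 1.0)))
            mut_rows.append(
                {
                    "patient_id": patient_id, "region_id": rid,
                    "chrom": meta["chrom"], "pos": meta["pos"],
                    "ref": meta["ref"], "alt": meta["alt"],
                    "ref_count": depth - alt_reads, "alt_count": alt_reads,
                    "gene": meta["gene"], "effect": meta["effect"],
                    "context": meta["context"], "germline_flag": meta["germline"],
                    "protein_change": meta["protein_change"],
                    "mutation_id": meta["mutation_id"],
                }
            )
    variants = pd.DataFrame(mut_rows) if mut_rows else _empty_variants()

    # --- immune profile -----------------------------------------------------
    if is_mmrd:
        inif_mu = config.inif_mmrd_mean
    elif is_wnt:
        inif_mu = config.inif_wnt_mean
    else:
        inif_mu = config.inif_mean
    mu01 = min(max(inif_mu / 100.0, 1e-3), 1 - 1e-3)
    kappa = config.inif_concentration
    ratio_mean = config.ratio_mean_wnt if is_wnt else config.ratio_mean_wt
    ratio_sigma = config.ratio_sigma_wnt if is_wnt else config.ratio_sigma_wt
    patient_ratio = float(
        rng.lognormal(np.log(ratio_mean) - 0.5 * ratio_sigma**2, ratio_sigma)
    )
    immune = {}
    for rid in region_ids:
        inif = float(100.0 * rng.beta(mu01 * kappa, (1 - mu01) * kappa))
        lam_f = config.foxp3_base_count + 2.0 * inif
        foxp3 = int(rng.poisson(lam_f))
        cd8 = int(rng.poisson(patient_ratio * lam_f))
        cd4 = int(rng.poisson(0.8 * lam_f))
        immune[rid] = {
            "inif_percent": round(inif, 2), "cd8": cd8, "cd4": cd4, "foxp3": foxp3,
        }

    n_nonsilent = int((variants.drop_duplicates("mutation_id")["effect"] != "silent").sum())
    neo_total = int(rng.poisson(config.neoantigen_rate * n_nonsilent))
    neo_clonal = int(rng.binomial(neo_total, config.clonal_neoantigen_fraction))

    flags = {
        "wnt_activated": is_wnt,
        "mmrd": is_mmrd,
        "wgd": wgd,
        "gleason": int(rng.choice([7, 8, 9, 10], p=[0.3, 0.35, 0.3, 0.05])),
        "fga_target": round(fga_target, 4),
        "n_clones": n_clones,
        "patient_ratio": round(patient_ratio, 4),
        "neoantigen_burden": neo_total,
        "clonal_neoantigen_burden": neo_clonal,
    }
    return PatientBundle(
        patient_id=patient_id, group=group, variants=variants, segments=segments,
        purity=purity, immune=immune, truth=truth, flags=flags,
    )


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Simulate independent patients under one config (empty config -> empty cohort)."""
    config.validate()
    n_met = int(round(config.frac_metastatic * config.n_patients))
    groups = ["mHNPC"] * n_met + ["hrlPC"] * (config.n_patients - n_met)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients = []
    for i, (grp, ss) in enumerate(zip(groups, seeds)):
        pid = f"P{i + 1:04d}"
        sub = int(ss.generate_state(1)[0] % (2**31 - 1))
        patients.append(simulate_patient(config, sub, patient_id=pid, group=grp))
    return CohortBundle(config=config, patients=patients)
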