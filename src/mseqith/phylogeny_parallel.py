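"""Clone-tree reconstruction, driver-event timing and parallel evolution.

Clone trees are built over mutation clusters using the two standard
multi-region constraints on cancer cell fractions:

* **crossing rule** — a child's CCF cannot exceed its parent's CCF in any
  region (beyond tolerance);
* **pigeonhole / sum rule** — the CCFs of sibling clones cannot sum to more
  than their parent's CCF in any region (beyond tolerance).

Reconstruction is greedy constrained attachment (clusters processed in
decreasing total CCF; each attaches to the deepest admissible parent), with
branching when several parents tie at maximal depth — every admissible
greedy tree is returned and the count reported, since multi-region data
need not determine a unique history. A brute-force enumerator over all
parent assignments is exposed for small instances.

Parallel evolution is flagged when one gene (or a configured pathway gene
set) carries two or more distinct non-silent variants assigned to pairwise
non-ancestral clones whose per-region CCFs are mutually exclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ccf_clustering import MutationCluster

__all__ = [
    "CloneTree",
    "ParallelEvent",
    "DEFAULT_TOLERANCE",
    "WNT_PATHWAY_GENES",
    "build_clone_tree",
    "enumerate_admissible_trees",
    "tree_satisfies_constraints",
    "detect_parallel_evolution",
    "time_driver_events",
]

#: Absolute CCF slack absorbed by both rules (binomial noise at depth ~100).
DEFAULT_TOLERANCE = 0.05

#: Default Wnt-pathway gene set for pathway-scoped parallel-evolution scans.
WNT_PATHWAY_GENES = ["CTNNB1", "APC", "RSPO2", "RNF43", "ZNRF3"]


@dataclass
class CloneTree:
    """Rooted tree over mutation clusters for one patient."""

    patient_id: str
    nodes: list[int]
    parent: dict[int, int | None]  # root maps to None
    ccf: dict[int, np.ndarray]
    n_mutations: dict[int, int] = field(default_factory=dict)

    @property
    def root(self) -> int:
        return next(n for n, p in self.parent.items() if p is None)

    def children(self, node: int) -> list[int]:
        return [n for n, p in self.parent.items() if p == node]

    def depth(self, node: int) -> int:
        d = 0
        while self.parent[node] is not None:
            node = self.parent[node]
            d += 1
        return d

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff a is a (strict) ancestor of b."""
        node = self.parent[b]
        while node is not None:
            if node == a:
                return True
            node = self.parent[node]
        return False

    def to_newick(self) -> str:
        def rec(node: int) -> str:
            kids = sorted(self.children(node))
            label = str(node)
            if not kids:
                return label
            return "(" + ",".join(rec(k) for k in kids) + ")" + label

        return rec(self.root) + ";"


@dataclass
class ParallelEvent:
    """Independent variants of one gene in mutually exclusive clones."""

    gene: str
    variants: list[dict]
    clone_ids: list[int]
    pathway: str | None = None


def tree_satisfies_constraints(tree: CloneTree, tolerance: float = DEFAULT_TOLERANCE) -> bool:
    """Check the crossing and sibling-sum rules in every region of every node."""
    for node in tree.nodes:
        kids = tree.children(node)
        if not kids:
            continue
        parent_ccf = tree.ccf[node]
        for k in kids:
            if np.any(tree.ccf[k] > parent_ccf + tolerance):
                return False
        sib_sum = np.sum([tree.ccf[k] for k in kids], axis=0)
        if np.any(sib_sum > parent_ccf + tolerance):
            return False
    return True


def _pick_root(clusters: list[MutationCluster]) -> MutationCluster:
    clonal = [c for c in clusters if c.clonality == "clonal"]
    if not clonal:
        raise ValueError("no trunk: no cluster is clonal (CCF ~ 1 in every region)")
    return max(clonal, key=lambda c: float(np.min(c.ccf)))


def build_clone_tree(
    clusters: list[MutationCluster],
    *,
    patient_id: str = "",
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[CloneTree]:
    """Greedy constrained attachment of clusters into clone trees.

    Clusters are attached in order of decreasing total CCF, each to the
    deepest parent satisfying both rules in every region; ties at maximal
    depth branch the search, so the result is the list of all greedy-
    admissible trees (length 1 when the data determine the attachment).
    Raises when no cluster is clonal ("no trunk") or a cluster fits under
    no parent, naming the violated constraint.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    root = _pick_root(clusters)
    rest = sorted(
        (c for c in clusters if c.cluster_id != root.cluster_id),
        key=lambda c: -float(np.sum(c.ccf)),
    )
    ccf = {c.cluster_id: np.asarray(c.ccf, dtype=float) for c in clusters}
    n_mut = {c.cluster_id: c.n_mutations for c in clusters}
    nodes = [c.cluster_id for c in clusters]

    def admissible_parents(parent_map: dict[int, int | None], cid: int) -> list[int]:
        placed = list(parent_map)
        out = []
        for cand in placed:
            if np.any(ccf[cid] > ccf[cand] + tolerance):
                continue
            sibs = [n for n, p in parent_map.items() if p == cand]
            sib_sum = ccf[cid] + (
                np.sum([ccf[s] for s in sibs], axis=0) if sibs else 0.0
            )
            if np.any(sib_sum > ccf[cand] + tolerance):
                continue
            out.append(cand)
        return out

    def depth_of(parent_map: dict[int, int | None], node: int) -> int:
        d = 0
        while parent_map[node] is not None:
            node = parent_map[node]
            d += 1
        return d

    partial: list[dict[int, int | None]] = [{root.cluster_id: None}]
    for c in rest:
        nxt: list[dict[int, int | None]] = []
        for pm in partial:
            cands = admissible_parents(pm, c.cluster_id)
            if not cands:
                continue
            depths = {p: depth_of(pm, p) for p in cands}
            dmax = max(depths.values())
            for p in (x for x in cands if depths[x] == dmax):
                new = dict(pm)
                new[c.cluster_id] = p
                nxt.append(new)
        if not nxt:
            # diagnose on the first partial tree for the error message
            viol = _describe_violation(partial[0], c.cluster_id, ccf, tolerance)
            raise ValueError(
                f"cluster {c.cluster_id} cannot attach under any parent: {viol}"
            )
        partial = nxt

    trees = []
    seen = set()
    for pm in partial:
        key = tuple(sorted((k, v) for k, v in pm.items()))
        if key in seen:
            continue
        seen.add(key)
        trees.append(
            CloneTree(
                patient_id=patient_id,
                nodes=list(nodes),
                parent=pm,
                ccf=ccf,
                n_mutations=n_mut,
            )
        )
    return trees


def _describe_violation(
    parent_map: dict[int, int | None],
    cid: int,
    ccf: dict[int, np.ndarray],
    tolerance: float,
) -> str:
    msgs = []
    for cand in parent_map:
        over = np.nonzero(ccf[cid] > ccf[cand] + tolerance)[0]
        if len(over):
            msgs.append(
                f"under parent {cand}: child CCF exceeds parent in region index {int(over[0])}"
            )
        else:
            sibs = [n for n, p in parent_map.items() if p == cand]
            sib_sum = ccf[cid] + (np.sum([ccf[s] for s in sibs], axis=0) if sibs else 0.0)
            over = np.nonzero(sib_sum > ccf[cand] + tolerance)[0]
            if len(over):
                msgs.append(
                    f"under parent {cand}: sibling CCF sum exceeds parent in region index {int(over[0])}"
                )
    return "; ".join(msgs) or "no candidate parents"


def enumerate_admissible_trees(
    clusters: list[MutationCluster],
    *,
    patient_id: str = "",
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[CloneTree]:
    """All rooted trees over the clusters satisfying both CCF rules.

    Brute force over every parent assignment; intended for small instances
    (<= ~7 clusters) and as the reference set for the greedy builder.
    """
    root = _pick_root(clusters)
    others = [c.cluster_id for c in clusters if c.cluster_id != root.cluster_id]
    ccf = {c.cluster_id: np.asarray(c.ccf, dtype=float) for c in clusters}
    n_mut = {c.cluster_id: c.n_mutations for c in clusters}
    nodes = [c.cluster_id for c in clusters]
    candidates = [nodes] * len(others)
    trees = []
    for assignment in itertools.product(*candidates):
        pm: dict[int, int | None] = {root.cluster_id: None}
        for cid, par in zip(others, assignment):
            if cid == par:
                break
            pm[cid] = par
        else:
            if not _is_connected_tree(pm, root.cluster_id):
                continue
            tree = CloneTree(
                patient_id=patient_id, nodes=nodes, parent=pm, ccf=ccf, n_mutations=n_mut
            )
            if tree_satisfies_constraints(tree, tolerance):
                trees.append(tree)
    return trees


def _is_connected_tree(parent_map: dict[int, int | None], root: int) -> bool:
    for node in parent_map:
        seen = set()
        cur = node
        while cur is not None:
            if cur in seen:
                return False  # cycle
            seen.add(cur)
            cur = parent_map[cur]
        if root not in seen:
            return False
    return True


def detect_parallel_evolution(
    variants: pd.DataFrame,
    assignment_by_mutation: dict,
    tree: CloneTree,
    *,
    gene_sets: dict[str, list[str]] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[ParallelEvent]:
    """Find genes (and configured pathways) hit independently in separate clones.

    A gene qualifies when >= 2 distinct non-silent variants are assigned to
    pairwise non-ancestral clones and, in every region, the implicated
    clones' CCFs sum to at most 1 + tolerance (mutual exclusivity — the
    clones occupy disjoint cell populations). ``variants`` is the
    one-row-per-mutation table (patient union); ``assignment_by_mutation``
    maps mutation id -> cluster id.
    """
    events: list[ParallelEvent] = []
    nonsilent = variants[variants["effect"] != "silent"]
    scopes: list[tuple[str, str | None, pd.DataFrame]] = [
        (gene, None, grp)
        for gene, grp in nonsilent[nonsilent["gene"] != ""].groupby("gene", sort=False)
    ]
    for pathway, genes in (gene_sets or {}).items():
        grp = nonsilent[nonsilent["gene"].isin(genes)]
        if len(grp):
            scopes.append((pathway, pathway, grp))

    for name, pathway, grp in scopes:
        recs = []
        for _, row in grp.iterrows():
            mid = row["mutation_id"]
            if mid not in assignment_by_mutation:
                continue
            recs.append((mid, assignment_by_mutation[mid], row))
        clone_ids = sorted({cid for _, cid, _ in recs})
        if len({mid for mid, _, _ in recs}) < 2 or len(clone_ids) < 2:
            continue
        # largest subset of pairwise non-ancestral clones carrying variants
        best: list[int] = []
        for r in range(len(clone_ids), 1, -1):
            for combo in itertools.combinations(clone_ids, r):
                if any(
                    tree.is_ancestor(a, b) or tree.is_ancestor(b, a)
                    for a, b in itertools.combinations(combo, 2)
                ):
                    continue
                sib_sum = np.sum([tree.ccf[c] for c in combo], axis=0)
                if np.any(sib_sum > 1.0 + tolerance):
                    continue
                best = list(combo)
                break
            if best:
                break
        if len(best) < 2:
            continue
        var_list = [
            {k: row[k] for k in ("mutation_id", "chrom", "pos", "ref", "alt", "gene", "effect") if k in row}
            for mid, cid, row in recs
            if cid in best
        ]
        if len({v["mutation_id"] for v in var_list}) < 2:
            continue
        events.append(
            ParallelEvent(gene=name, variants=var_list, clone_ids=best, pathway=pathway)
        )
    return events


def time_driver_events(
    driver_genes: list[str],
    snv_events: pd.DataFrame,
    scna_events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cohort-level early/late tally per driver gene.

    ``snv_events`` has columns (patient_id, gene, clonality) with clonality
    in {clonal, subclonal}; ``scna_events`` has (patient_id, gene, status)
    with status in {ubiquitous, heterogeneous} — ubiquitous counts as early
    alongside clonal SNVs. Returns per gene: event counts and the fraction
    of early (clonal/ubiquitous) events; genes with no events are omitted.
    """
    rows = []
    for gene in driver_genes:
        early = late = 0
        snv = snv_events[snv_events["gene"] == gene]
        early += int((snv["clonality"] == "clonal").sum())
        late += int((snv["clonality"] == "subclonal").sum())
        if scna_events is not None and len(scna_events):
            scna = scna_events[scna_events["gene"] == gene]
            early += int((scna["status"] == "ubiquitous").sum())
            late += int((scna["status"] == "heterogeneous").sum())
        total = early + late
        if total == 0:
            continue
        rows.append(
            {
                "gene": gene,
                "n_events": total,
                "n_clonal": early,
                "n_subclonal": late,
                "fraction_clonal": early / total,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_events", "n_clonal", "n_subclonal", "fraction_clonal"])
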