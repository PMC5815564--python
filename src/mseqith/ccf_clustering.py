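"""Cancer cell fraction estimation and multi-region mutation clustering.

The cancer cell fraction (CCF) of a mutation in a tumour region is the
fraction of cancer cells in that region carrying the mutation. For a sample
with purity ``rho``, local total copy number ``CN_t`` and mutation
multiplicity ``m`` (copies of the mutant allele per carrying cell), the
expected variant allele fraction is

    E[VAF] = ccf * rho * m / (rho * CN_t + 2 * (1 - rho))

Inverting this relation gives a per-site CCF point estimate; jointly
modelling all mutations of a patient across regions as a finite mixture of
binomials — each component carrying one CCF parameter per region — groups
mutations into subclones. The mixture is fitted by EM with an exact
per-component M-step (the weighted binomial log-likelihood is concave in
the CCF, solved by vectorised bisection on the score), with multi-start
initialisation and BIC model selection over the number of components.
This is a deterministic, seed-controlled stand-in for Dirichlet-process
MCMC clustering tools used for the same task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "CCFEstimate",
    "MutationCluster",
    "ClusteringResult",
    "estimate_multiplicity",
    "expected_vaf",
    "compute_ccf",
    "cluster_mutations",
    "classify_clonality",
    "posterior_assignments",
]

#: CCF point estimates above 1 flag copy-number/purity inconsistency; they
#: are clipped to this ceiling before clustering rather than discarded.
CCF_CEILING = 1.5

#: Per-region CCF at or above which a cluster is called clonal everywhere.
DEFAULT_CLONAL_THRESHOLD = 0.9


@dataclass
class CCFEstimate:
    """Per-mutation, per-region CCF point estimate with a credible interval."""

    mutation_id: str
    region_id: str
    vaf: float
    multiplicity: int
    ccf: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95


@dataclass
class MutationCluster:
    """A set of mutations sharing one per-region CCF vector (a subclone)."""

    cluster_id: int
    members: list
    ccf: np.ndarray  # shape (n_regions,), in [0, 1]
    clonality: str = "subclonal"

    @property
    def n_mutations(self) -> int:
        return len(self.members)


@dataclass
class ClusteringResult:
    clusters: list[MutationCluster]
    assignments: np.ndarray  # mutation index -> cluster_id
    log_likelihood: float
    bic: float
    n_clusters: int
    loglik_history: list[float] = field(default_factory=list)
    converged: bool = True
    bic_by_k: dict[int, float] = field(default_factory=dict)


def estimate_multiplicity(
    vaf: float, purity: float, cn_total: int, cn_major: int
) -> int:
    """Estimate the number of mutant-allele copies per carrying cell.

    ``m = clip(round(vaf * (rho*CN_t + 2*(1-rho)) / rho), 1, cn_major)``.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if cn_total < 1:
        raise ValueError(f"cn_total must be >= 1, got {cn_total}")
    if cn_major == 0:
        raise ValueError("cn_major = 0 at a mutated site is inconsistent")
    raw = vaf * (purity * cn_total + 2.0 * (1.0 - purity)) / purity
    return int(np.clip(np.round(raw), 1, cn_major))


def expected_vaf(ccf: float, purity: float, cn_total: float, m: int) -> float:
    """Expected variant allele fraction under the standard purity/CN model."""
    return ccf * purity * m / (purity * cn_total + 2.0 * (1.0 - purity))


def compute_ccf(
    alt_count: int,
    ref_count: int,
    purity: float,
    cn_total: int,
    m: int,
    *,
    mutation_id: str = "",
    region_id: str = "",
    level: float = 0.95,
) -> CCFEstimate:
    """Point estimate and binomial credible interval for one site's CCF.

    The VAF-to-CCF transformation is ``ccf = vaf * (rho*CN_t + 2*(1-rho)) /
    (rho * m)``. The interval is the Clopper–Pearson interval on the binomial
    proportion pushed through the (fixed) transformation, so ``alt_count = 0``
    yields a lower bound of exactly 0. Estimates are clipped to
    ``[0, CCF_CEILING]``; values above 1 indicate purity or copy-number
    inconsistency and are retained (clipped) rather than dropped.
    """
    if purity <= 0.0:
        raise ValueError("purity must be positive")
    depth = alt_count + ref_count
    if depth <= 0:
        raise ValueError("depth must be positive to estimate a CCF")
    vaf = alt_count / depth
    factor = (purity * cn_total + 2.0 * (1.0 - purity)) / (purity * m)
    alpha = 1.0 - level
    if alt_count == 0:
        p_lo = 0.0
    else:
        p_lo = stats.beta.ppf(alpha / 2.0, alt_count, ref_count + 1)
    if ref_count == 0:
        p_hi = 1.0
    else:
        p_hi = stats.beta.ppf(1.0 - alpha / 2.0, alt_count + 1, ref_count)
    ccf = float(np.clip(vaf * factor, 0.0, CCF_CEILING))
    lo = float(np.clip(p_lo * factor, 0.0, CCF_CEILING))
    hi = float(np.clip(p_hi * factor, 0.0, CCF_CEILING))
    return CCFEstimate(
        mutation_id=mutation_id,
        region_id=region_id,
        vaf=vaf,
        multiplicity=m,
        ccf=ccf,
        ci_lower=lo,
        ci_upper=hi,
        level=level,
    )


def classify_clonality(
    ccf_vector: np.ndarray, threshold: float = DEFAULT_CLONAL_THRESHOLD
) -> str:
    """A cluster is clonal iff its CCF reaches ``threshold`` in every region."""
    return "clonal" if np.all(np.asarray(ccf_vector) >= threshold) else "subclonal"


def _conversion_factor(
    alt: np.ndarray,
    depth: np.ndarray,
    purity: np.ndarray,
    cn_total: np.ndarray,
    cn_major: np.ndarray,
) -> np.ndarray:
    """Per-site VAF = c * CCF factor, with multiplicity from the observed VAF."""
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    denom = purity[None, :] * cn_total + 2.0 * (1.0 - purity[None, :])
    m_raw = np.round(vaf * denom / purity[None, :])
    mult = np.clip(m_raw, 1, np.maximum(cn_major, 1))
    return purity[None, :] * mult / denom


def posterior_assignments(
    alt: np.ndarray,
    depth: np.ndarray,
    purity: np.ndarray,
    cn_total: np.ndarray,
    cn_major: np.ndarray,
    clusters: list["MutationCluster"],
) -> np.ndarray:
    """Maximum-posterior cluster ids for mutations under fitted clusters.

    Lets a model fitted on a subsample label the full mutation set. Mixture
    weights are taken proportional to cluster sizes; ties break toward the
    lowest cluster id.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    purity = np.asarray(purity, dtype=float)
    c = _conversion_factor(alt, depth, purity, np.asarray(cn_total, float), np.asarray(cn_major, float))
    order = sorted(clusters, key=lambda cl: cl.cluster_id)
    phi = np.vstack([np.asarray(cl.ccf, dtype=float) for cl in order])
    sizes = np.array([max(cl.n_mutations, 1) for cl in order], dtype=float)
    log_pi = np.log(sizes / sizes.sum())
    ll = _binom_loglik_terms(alt, depth, c, phi) + log_pi[None, :]
    ids = np.array([cl.cluster_id for cl in order])
    return ids[np.argmax(ll, axis=1)]


# -- EM for the multi-region binomial mixture ---------------------------------


def _binom_const(alt: np.ndarray, depth: np.ndarray) -> float:
    """Summed log binomial coefficients (phi-independent part of the loglik)."""
    return float(
        (gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)).sum()
    )


def _binom_loglik_terms(
    alt: np.ndarray, depth: np.ndarray, c: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Per-mutation, per-cluster log-likelihood summed over regions.

    ``alt, depth, c`` have shape (M, R); ``phi`` has shape (K, R). Returns
    (M, K), excluding the phi-independent binomial coefficient (add
    ``_binom_const`` for the absolute likelihood).
    """
    p = np.clip(c[:, None, :] * phi[None, :, :], 1e-12, 1.0 - 1e-12)  # (M,K,R)
    a = alt[:, None, :]
    d = depth[:, None, :]
    ll = a * np.log(p) + (d - a) * np.log1p(-p)
    return ll.sum(axis=2)


def _mstep_phi(
    gamma: np.ndarray,
    alt: np.ndarray,
    depth: np.ndarray,
    c: np.ndarray,
    n_bisect: int = 30,
) -> np.ndarray:
    """Exact per-(cluster, region) maximiser of the weighted binomial loglik.

    The weighted log-likelihood in phi is concave (sum of concave terms), so
    its score is monotone decreasing; the root is found by vectorised
    bisection on [0, 1]. Closed-form boundary cases: no weighted alt reads ->
    phi = 0; score still positive at phi = 1 -> phi = 1.
    """
    K = gamma.shape[1]
    R = alt.shape[1]
    A = gamma.T @ alt  # (K, R): weighted alt-read totals
    w = (depth - alt) * c  # (M, R)
    cm = c[:, None, :]
    wm = w[:, None, :]

    def score(phi: np.ndarray) -> np.ndarray:
        # d/dphi sum_i gamma_ik [a log(c phi) + (d - a) log(1 - c phi)]
        denom = np.maximum(1.0 - cm * phi[None, :, :], 1e-12)  # (M,K,R)
        t = np.einsum("mk,mkr->kr", gamma, wm / denom)
        with np.errstate(divide="ignore"):
            return A / np.maximum(phi, 1e-300) - t

    lo = np.full((K, R), 1e-12)
    hi = np.ones((K, R))
    # clusters/regions with zero weighted alt mass collapse to phi = 0
    zero_mask = A <= 0
    at_upper = score(hi) >= 0
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        take_hi = score(mid) > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    phi = 0.5 * (lo + hi)
    phi[at_upper] = 1.0
    phi[zero_mask] = 0.0
    return phi


def _fit_em(
    alt: np.ndarray,
    depth: np.ndarray,
    c: np.ndarray,
    k: int,
    init_phi: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[float], bool]:
    """Run EM from an initial phi; returns (pi, phi, gamma, loglik, history, conv)."""
    M = alt.shape[0]
    pi = np.full(k, 1.0 / k)
    phi = init_phi.copy()
    history: list[float] = []
    converged = False
    gamma = np.full((M, k), 1.0 / k)
    loglik = -np.inf
    const = _binom_const(alt, depth)
    for _ in range(max_iter):
        log_terms = _binom_loglik_terms(alt, depth, c, phi)  # (M, K)
        weighted = log_terms + np.log(np.maximum(pi, 1e-300))[None, :]
        norm = logsumexp(weighted, axis=1)
        loglik = float(norm.sum()) + const
        history.append(loglik)
        gamma = np.exp(weighted - norm[:, None])
        pi = gamma.mean(axis=0)
        phi = _mstep_phi(gamma, alt, depth, c)
        if len(history) >= 2 and abs(history[-1] - history[-2]) < tol * (
            1.0 + abs(history[-2])
        ):
            converged = True
            break
    return pi, phi, gamma, loglik, history, converged


def _point_ccfs(alt: np.ndarray, depth: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-site CCF point estimates used for initialisation, clipped to [0, 1]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        x = np.where(c > 0, vaf / np.maximum(c, 1e-12), 0.0)
    return np.clip(x, 0.0, 1.0)


def cluster_mutations(
    alt: np.ndarray,
    depth: np.ndarray,
    purity: np.ndarray,
    cn_total: np.ndarray,
    cn_major: np.ndarray,
    *,
    max_clusters: int = 6,
    n_restarts: int = 10,
    seed: int = 0,
    mutation_ids: list | None = None,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
) -> ClusteringResult:
    """Cluster one patient's mutations across regions into subclones.

    Parameters
    ----------
    alt, depth : (M, R) int arrays
        Alt read counts and total depth for every mutation in every region.
        Zero alt reads in a region are informative and contribute a binomial
        term (absence of a subclone from a region is evidence).
    purity : (R,) array
        Per-region tumour purity in (0, 1].
    cn_total, cn_major : (M, R) int arrays
        Local total and major allele-specific copy number at each site.
    max_clusters : int
        BIC model selection runs over K = 1..max_clusters.
    n_restarts : int
        Seed-controlled multi-start per K (k-means-style initialisation from
        per-site CCF estimates plus jitter); the best likelihood wins.

    Returns
    -------
    ClusteringResult
        Clusters with per-region CCF vectors (projected to [0, 1]),
        maximum-posterior assignments (ties broken toward the lowest cluster
        index), and the BIC trace. Non-convergence raises a warning and the
        best solution found is returned flagged.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.ndim != 2 or alt.shape != depth.shape:
        raise ValueError("alt and depth must be (n_mutations, n_regions) arrays")
    M, R = alt.shape
    if M < 1 or R < 1:
        raise ValueError("need at least one mutation and one region")
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    purity = np.asarray(purity, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purities must be in (0, 1]")
    cn_total = np.asarray(cn_total, dtype=float)
    cn_major = np.asarray(cn_major, dtype=float)

    # per-site multiplicity from the observed VAF, then the VAF = c * ccf
    # factor; c <= 1 always since m <= CN_t
    c = _conversion_factor(alt, depth, purity, cn_total, cn_major)

    x = _point_ccfs(alt, depth, c)
    rng = np.random.default_rng(seed)
    kmax = min(max_clusters, M)

    from sklearn.cluster import KMeans

    best = None
    bic_by_k: dict[int, float] = {}
    for k in range(1, kmax + 1):
        best_k = None
        n_hits = 0  # restarts reproducing the current best optimum
        for j in range(n_restarts):
            sub = int(rng.integers(0, 2**31 - 1))
            if k == 1:
                init_phi = x.mean(axis=0, keepdims=True)
            else:
                km = KMeans(n_clusters=k, n_init=1, random_state=sub)
                labels = km.fit_predict(x + rng.normal(0, 1e-6, size=x.shape))
                init_phi = np.vstack(
                    [
                        x[labels == kk].mean(axis=0)
                        if np.any(labels == kk)
                        else rng.uniform(0, 1, size=R)
                        for kk in range(k)
                    ]
                )
                if j > 0:  # jitter subsequent restarts to escape local optima
                    init_phi = np.clip(
                        init_phi + rng.normal(0, 0.05 * j, size=init_phi.shape),
                        0.0,
                        1.0,
                    )
            fit = _fit_em(alt, depth, c, k, init_phi)
            if best_k is None or fit[3] > best_k[3] + 1e-6 * (1 + abs(best_k[3])):
                best_k = fit
                n_hits = 1
            elif abs(fit[3] - best_k[3]) <= 1e-4 * (1 + abs(best_k[3])):
                n_hits += 1
            if k == 1:
                break  # single component: M-step is exact, restarts identical
            if n_hits >= 3 and j >= 3:
                break  # optimum reproduced by independent starts; stop early
        pi, phi, gamma, loglik, history, converged = best_k
        n_params = (k - 1) + k * R
        bic = -2.0 * loglik + n_params * np.log(M)
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, pi, phi, gamma, loglik, history, converged)

    bic, k, pi, phi, gamma, loglik, history, converged = best
    if not converged:
        warnings.warn(
            f"EM did not converge for K={k}; returning best solution found",
            RuntimeWarning,
        )
    assignments = np.argmax(gamma, axis=1)  # argmax -> lowest index on ties

    ids = mutation_ids if mutation_ids is not None else list(range(M))
    clusters = []
    kept = sorted(set(assignments.tolist()))
    remap = {old: new for new, old in enumerate(kept)}
    for old in kept:
        members = [ids[i] for i in range(M) if assignments[i] == old]
        ccf_vec = np.clip(phi[old], 0.0, 1.0)
        clusters.append(
            MutationCluster(
                cluster_id=remap[old],
                members=members,
                ccf=ccf_vec,
                clonality=classify_clonality(ccf_vec, clonal_threshold),
            )
        )
    assignments = np.array([remap[a] for a in assignments])
    return ClusteringResult(
        clusters=clusters,
        assignments=assignments,
        log_likelihood=loglik,
        bic=bic,
        n_clusters=len(clusters),
        loglik_history=history,
        converged=converged,
        bic_by_k=bic_by_k,
    )
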