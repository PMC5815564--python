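# Methods

`mseqith` analyses multi-region tumour sequencing data — several spatially
separated biopsies of one tumour per patient — to quantify intratumoural
heterogeneity (ITH) and reconstruct each tumour's clonal history, and links
the genotype calls to immune-infiltrate measurements. This note documents
the models, the synthetic-data generator used to validate them, and the
numerical choices, in enough detail to reproduce or audit any stage.

## Cancer cell fractions and the clustering model

For a mutation with variant allele fraction (VAF) `v` at a site with tumour
purity `ρ`, local total copy number `CN_t` and mutant-allele multiplicity
`m`, the expected VAF is

    E[v] = φ · ρ · m / (ρ · CN_t + 2(1 − ρ))

where `φ` is the cancer cell fraction (CCF). Multiplicity is estimated per
site as `m = clip(round(v(ρ·CN_t + 2(1−ρ))/ρ), 1, CN_major)`; CCF point
estimates invert the VAF relation, carry a Clopper–Pearson binomial
interval pushed through the (fixed) transformation, and are clipped to
[0, 1.5] — values above 1 flag purity/copy-number inconsistency and are
retained, not dropped.

Mutations of one patient are clustered across regions with a finite mixture
of binomials: component `k` has one CCF parameter per region, and a
mutation contributes a binomial likelihood term in every region, including
regions with zero alt reads (absence is evidence). The mixture is fitted by
EM. The per-component M-step maximises a weighted binomial log-likelihood
that is concave in `φ`; the root of its score is found by vectorised
bisection (30 iterations on [0, 1]), so the M-step is exact and the
log-likelihood is non-decreasing across iterations (asserted in tests).
Initialisation is k-means on per-site CCF estimates with seeded jittered
restarts (up to 10; restarts stop early once three independent starts
reproduce the best optimum). The number of components is chosen by BIC over
K = 1..K_max (default 6), with `(K−1) + K·R` parameters against the number
of mutations. Ties in posterior assignment break toward the lowest cluster
index; everything is deterministic given the seed. This deterministic
EM+BIC scheme stands in for Dirichlet-process MCMC tools often used for the
same task; at desk scale it recovers well-separated subclones exactly
(ARI = 1 at depth 100 in the recovery tests).

A cluster is **clonal** when its CCF is at least 0.9 in every region,
otherwise subclonal. For hypermutated patients the mixture is fitted on a
seeded subsample (default 400 mutations) and the remaining mutations are
labelled by maximum posterior under the fitted components.

## Presence classes and ITH metrics

A mutation is **present** in a region with ≥ 2 alt reads and VAF ≥ 0.02. A
region counts as an informative absence only if it is **assessable**: the
binomial probability of meeting the presence rule, were the mutation clonal
there (expected VAF from the purity/CN model), is at least 0.95. Against
the assessable region set, a mutation is *ubiquitous* (present in all),
*shared* (≥ 2 but not all) or *private* (exactly one); the three counts
always partition the called mutations. Without the power rule, shallow
regions masquerade as true absences and inflate the private count.

Exonic burden is distinct mutations in the patient union divided by the
exome footprint (default 30 Mb, configurable). Fraction of genome altered
(FGA) takes the union across regions of bases whose total copy number
differs from the neutral baseline — 2, or 4 in regions called whole-genome
doubled (WGD: more than half of covered bases with major CN ≥ 2) — over the
configured autosome total. Sex chromosomes are excluded from the
denominator by default (hemizygosity in a male cohort muddles the neutral
state). The heterogeneous-SCNA fraction works on breakpoint-union atoms
with per-region states in {loss, neutral, gain}: of the bases altered in
any region, the fraction not altered in the same direction in all regions.
Both quantities are invariant to splitting segments into abutting pieces
(property-tested). A per-region mean FGA variant is available behind a
flag; union is the default.

Group comparisons use a single Mann–Whitney U implementation: exact
distribution for tie-free data, full enumeration of the `C(n, n1)` group
assignments for tied data when min(n1, n2) ≤ 8, otherwise the normal
approximation with tie correction. Two-sided p is twice the smaller tail,
capped at 1. SNV-vs-SCNA heterogeneity correlation is Pearson's r with the
t-transform p-value.

## Clone trees and parallel evolution

Trees over clusters must satisfy, in every region, the crossing rule
(child CCF ≤ parent CCF) and the pigeonhole/sum rule (sibling CCFs sum to
at most the parent's), both with an absolute tolerance of 0.05 CCF —
roughly two standard errors of a 20-mutation cluster mean at depth 100.
Reconstruction is greedy: clusters in decreasing total CCF each attach to
the deepest admissible parent; equal-depth ties branch the search and every
admissible greedy tree is returned, because multi-region data need not
determine a unique history. A brute-force enumerator over all parent
assignments serves as the reference for small instances and in tests.
Downstream event timing uses only clonality calls, which are
tree-independent, so tree ambiguity is reported rather than resolved.

Parallel evolution is reported for any gene — or configured pathway gene
set, with a Wnt set (CTNNB1, APC, RSPO2, RNF43, ZNRF3) shipped — carrying
≥ 2 distinct non-silent variants in pairwise non-ancestral clones whose
CCFs sum to ≤ 1 + tolerance in every region (mutual exclusivity: the
clones occupy disjoint cell populations). On chain-topology truths with
realistic cluster-mean noise the detector reports zero events across 1,000
replicates; the trunk-plus-three-exclusive-subclones structure is recovered
with all three variants through the full read→cluster→tree→detect path.

## SCNA locus events and burden-controlled enrichment

A locus (1-based inclusive catalogue entry; approximate GRCh37 cytoband
defaults ship for 3q21.3, 3q26.2, 8q, 7p, 8p21, all user-overridable) is
carried by a region when ≥ 50% of it is covered by gained (or lost) bases;
patient status is ubiquitous / heterogeneous / absent by region
concordance. Group enrichment is the two-sided Fisher exact test on
present/absent.

High-burden patients hit any locus more often by chance, so the
burden-controlled test re-places each patient's altered segments uniformly
at random over valid genome positions (lengths and per-region counts
preserved), re-calls the locus and recomputes the group frequency
difference; `p = (1 + #{null ≥ observed})/(1 + n_perm)`. This conditions
exactly on per-patient altered-base burden and the segment-length spectrum.
Because the statistic is discrete the p-value is mildly conservative; with
25 patients and realistic segment counts it is calibrated to pass a KS
uniformity check under the null. The calibration holds when observed
segments follow the same placement law as the null (uniform over valid
positions); a generation law that biases placements toward short
chromosomes makes the test conservative, which is the safe direction.

## Mutational signatures

Spectra use the standard 96 trinucleotide context classes under the
pyrimidine-strand convention; purine-strand records are reverse-
complemented on counting (the fold is an involution). Decomposition onto a
catalogue (96 × k column-stochastic matrix) is nonnegative least squares on
the normalised spectrum with weights renormalised to a probability vector
and residual reported as cosine distance — deterministic and accurate to
±0.03 on 70/30 mixtures of 10,000 mutations. The built-in catalogue is
**synthetic**: a flat background, a `clock_like` column concentrated on C>T
at NpCpG (deamination-clock shape), and an `mmrd_like` column enriched for
C>T and T>C (mismatch-repair-deficiency shape). It exists so recovery tests
and the simulator need no download; it does not numerically reproduce any
published catalogue, and real analyses should supply their own catalogue
TSV. Signature attribution by clonality fits the ubiquitous and
non-ubiquitous mutation sets independently; sets under 20 mutations are
fitted but flagged low-confidence.

## Genotype flags and immune association

**Wnt activation**: any region with a CTNNB1 variant whose protein change
is in the configured exon-3 gain-of-function list (ships with p.S33P,
p.S33C, p.T41A), RSPO2 total CN at least twice the region's ploidy baseline
(4, or 8 under WGD), or a homozygous deletion (total CN 0) overlapping APC,
RNF43 or ZNRF3. **MMRD**: two independent hits on one mismatch-repair gene
(MLH1, MSH2, MSH6, PMS2) — a hit is a non-silent variant (germline or
somatic) or a distinct deletion with the minor allele fully lost
(minor CN 0); major CN 0 counts as both alleles gone; the same truncal
deletion seen in several regions is one event. Single-hit genes are
surfaced as monoallelic, explicitly not MMRD. Both flags are monotone in
evidence. Gene intervals are configuration (approximate GRCh37 defaults,
overridable via a BED-like TSV).

Immune summaries: the *extensive-infiltrate* flag fires when any region's
INIF exceeds 20% of nucleated cells; the *digital-analysis-eligible* flag
when any region reaches the cohort-median threshold (default 8, recomputed
from the cohort when requested). The patient CD8+/FOXP3+ ratio pools counts
(sum across eligible regions, then divide) — robust to zero FOXP3 in single
regions; per-region ratios are reported alongside and a mean-of-ratios
pooling is available. The ratio comparison between Wnt-activated and
wild-type patients restricts to digital-eligible patients and routes
through the shared Mann–Whitney implementation, as do all group tests.
Neoantigen burdens (externally supplied counts) are related to maximal INIF
by Spearman correlation.

## The synthetic cohort generator

The generator emulates a 25-patient multi-region biopsy cohort (12
metastatic-on-presentation, 13 high-risk localised; 2–4 regions; 2–6 clones
per tumour) and writes the same formats the readers consume plus a JSON
truth bundle. Defaults, with units and rationale:

- **Clone trees**: random topology (each clone's parent uniform among
  earlier clones); per-region CCFs by stick-breaking — children receive
  Dirichlet shares of the parent's CCF with one share retained — so the
  sum rule holds exactly by construction, with per-region clone dropout
  (p = 0.35) for region-specific mixtures and a guaranteed home region per
  clone so every clone is observable somewhere.
- **Reads**: depth ~ Poisson(100) floored at 1 per site and region
  (overdispersion-free by design; configurable); purity uniform on
  [0.4, 0.8]; alt counts binomial at the expected VAF; an internal
  invariant aborts if an expected VAF ever exceeds 1.
- **Copy number**: per-patient altered-genome fraction drawn from a
  truncated normal around the clinical-group mean (0.30 metastatic vs 0.12
  localised, sd 0.08, bounds [0.02, 0.45]) — the group FGA contrast is
  therefore known by construction; non-overlapping gain/loss segments with
  log-uniform lengths 10–80 Mb; half of events truncal, the rest on
  subclones detectable somewhere; WGD patients (p = 0.15) use a 2+2
  baseline. Segment tables fully partition each chromosome, so validation
  and WGD calling need no missing-data convention. The genome is the 22
  autosomes at ~GRCh37 lengths (megabase precision).
- **Mutations**: counts per clone uniform 5–30; hypermutated (MMRD)
  patients multiply counts by 12; contexts drawn from per-clone signature
  mixtures over the built-in catalogue (trunk clock-dominated by default;
  MMRD trunks 40% `mmrd_like`), emitted on the purine strand half the time
  to exercise folding; 10% of truncal mutations on gained segments carry
  multiplicity = major CN.
- **Planted genotypes**: Wnt-activated patients (p = 0.3) receive a CTNNB1
  gain-of-function variant; MMRD patients (p = 0.08) a truncal
  allele-losing deletion spanning MSH2/MSH6 plus a germline MSH6 variant —
  two hits, recoverable by the flag logic.
- **Immune model**: region INIF ~ Beta with mean 8% (30% for MMRD, 12% for
  Wnt) and concentration 8; patient CD8+/FOXP3+ ratio log-normal with mean
  6.08 (wild-type) or 2.65 (Wnt-activated) and log-scale sd 0.73 / 0.43,
  moment-matched to the observed group spreads; per-region counts Poisson
  around the patient ratio. Neoantigen burdens are Poisson in the
  non-silent mutation count (0.8 binders/mutation, 60% clonal), so they
  correlate with INIF only through the MMRD link, not directly.
- **Seeding**: one integer seed; per-patient substreams from spawned
  `numpy` SeedSequences; outputs are byte-identical across runs.

What the generator does **not** emulate: read-level artefacts (mapping
error, strand bias, FFPE damage), overdispersed depth, subclonal
(fractional) copy number, indels/fusions/structural variants, germline
contamination beyond flagged rows, and spatial correlation between
adjacent biopsies. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative model,
not robustness to real-data artefacts.

## Known limitations and honest caveats

- With the ratio dispersions moment-matched to the observed group spreads
  (log-sd 0.73 for wild-type), the exact Mann–Whitney test at 7-vs-8 has
  ~44% power for the 2.65-vs-6.08 ratio contrast; a single cohort of that
  size detecting it is partly fortunate. The acceptance suite reports this
  measured power rather than assuming a more optimistic noise level.
- Clone-number recovery degrades, as expected, for clones with low CCF in
  all regions or few mutations; BIC then merges them into neighbours. The
  occasional patient whose fitted trunk falls below the 0.9 clonal
  threshold yields no tree and is reported with a warning rather than
  forced.
- The burden-controlled permutation p is conservative on discrete
  statistics; with few patients or rare loci it loses power before it loses
  validity.
- Problem sizes in the test and acceptance runs (cohorts of 6–25 patients,
  10,000-site calibrations, 200-run calibration sweeps, 199–500
  permutations) were chosen to make every check rerun from scratch in a few
  minutes on one core while keeping Monte-Carlo error well inside the
  asserted tolerances.
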