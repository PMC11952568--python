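# Methods

`tumorchrono` reconstructs the evolutionary chronology of a tumor cohort
from somatic mutations, allele-specific copy number and purity: clonal
architecture, molecular timing of copy-number gains, chronological age of
the most recent common ancestor (MRCA) and the latency to diagnosis,
consensus driver ordering, signature activity dynamics, indel motif
analysis, and a hypoxia expression score.  A synthetic cohort generator
realizes the same generative assumptions the inference stages invert, so
every stage can be validated against known truth.

## Clonal architecture

**Read-count model.**  A mutation at multiplicity `m` (copies per tumor
cell) carried by a fraction `CCF` of tumor cells, in a segment with total
tumor copy number `n_tot`, at sample purity `rho`, has expected variant
allele fraction

    E[VAF] = m * rho * CCF / (rho * n_tot + 2 * (1 - rho)),

and alt reads are binomial at the locus depth.  The raw multiplicity is
`m_raw = VAF * (rho * n_tot + 2(1 - rho)) / rho`; the integer state is the
(m, CCF-cluster) pair maximizing the binomial likelihood, with `m` limited
to `1..major_cn` of the host segment.

**Power gating.**  NRPCC (reads per tumor chromosomal copy) is
`d * rho / (rho * psi + 2(1 - rho))`; samples with NRPCC <= 10 or purity
<= 0.3 are flagged ineligible for evolution analysis, the regime where
subclone detection is reliable for CCF above roughly 0.4.

**CCF clusters.**  A one-dimensional binomial mixture over cluster
locations `c_k` in (0, 1.2] is fitted by EM; the M-step solves the weighted
binomial score equation by safeguarded Newton (the score is strictly
decreasing, so the root is unique).  The cluster count 1..4 is selected by
BIC with ties broken toward fewer clusters; each k adds one random restart
to the deterministic quantile initialization.  The clonal cluster is the
one nearest CCF 1.0, not necessarily the largest.  A "detected subclone"
is a non-clonal cluster below CCF 0.8 carrying at least 2% of mutations;
the 0.8 cutoff matches the eligibility rule used for driver ordering.
CCFs are capped at 1.2.  Below 50 mutations the fit falls back to a single
cluster with a warning.

**Clonality classes.**  In a clonally gained segment (major CN >= 2,
clonal fraction 1), clonal mutations at m >= 2 predate the gain (early
clonal) and m = 1 mutations postdate it (late clonal); clonal mutations in
un-gained segments are "clonal unspecified"; mutations in lower-CCF
clusters are subclonal.

**Gain timing.**  For the canonical states (2,1), (2,2) and (2,0), a gain
at molecular time `pi` under a constant per-copy rate leaves duplicated
(m=2) and unduplicated (m=1) clonal mutation counts with expectations
proportional to (pi, 3-2pi), (2pi, 4(1-pi)) and (pi, 2(1-pi))
respectively.  The profile-Poisson MLE is closed-form:

    pi_hat = 3 n2 / (n1 + 2 n2)   for (2,1)
    pi_hat = 2 n2 / (n1 + 2 n2)   for (2,2) and (2,0)

clamped to [0,1], with a 200-resample percentile bootstrap CI over the
mutation labels.  Segments in other states, or with fewer than 5
informative mutations, are recorded untimed.  Higher copy states are out
of scope.

**WGD.**  Whole-genome duplication is called when ploidy >= 2.9 - 2 * LOH
fraction (boundary inclusive; the source rule does not state strictness).
LOH fraction and the major-CN>=2 fraction are length-weighted over
autosomes only.

## Chronological clock

Clock-like mutations are C>T substitutions at CpG dinucleotides in an
NpCpG context (the SBS1 process), assumed to accumulate at `mu` mutations
per year per diploid genome before the MRCA and `a * mu` after it
(acceleration `a`, default scenarios {1, 2.5, 5, 7.5, 10}; headline
outputs use a = 1).

**Burden adjustment.**  The pre-MRCA burden is the multiplicity-weighted
clonal clock count scaled to a diploid genome, `B_pre = (2/psi_bar) *
sum(m_i)` with `psi_bar` the length-weighted mean autosomal copy number.
Weighting by multiplicity makes the adjusted count proportional to elapsed
time regardless of when a gain occurred: a pre-gain mutation on two copies
marks two copies' worth of mutation time, exactly compensating the faster
post-gain accrual that the `2/psi_bar` scaling divides out.  The post-MRCA
burden weights each subclonal clock mutation by its CCF
(`B_post = (2/psi_bar) * sum(CCF_i)`): under neutral growth the n(u)
concurrent lineages at time u each accrue mu per year while each new
mutation reaches ~1/n(u) of final cells, so the CCF sum is an unbiased
estimate of the per-lineage count.  Sex-chromosome mutations are excluded
from both burdens and from psi_bar.

**MRCA and latency.**  With age at diagnosis A, the burdens obey
`B_pre / B_post = t / (a (A - t))`, giving

    t_MRCA = A * a * B_pre / (B_post + a * B_pre),    latency = A - t_MRCA.

The estimate is invariant to scaling both burdens, latency is
non-increasing in `a`, and B_post = 0 puts the MRCA at diagnosis
(latency 0).  CIs propagate Poisson uncertainty in both burdens by
resampling.  A negative solved age (impossible here by construction) would
be clamped to 0 with a flag.

**Rate calibration.**  The cohort rate is fitted by an empirical-Bayes
random-slope model through the origin: per-group through-origin slopes
with pooled residual variance, then maximum-likelihood partial pooling of
group slopes toward the global mean (random-effects meta-analysis).  This
deliberately replaces a full hierarchical Bayesian treatment; validation
is parameter recovery, not posterior equivalence.  The regression is
forced through the origin (zero burden at age zero); groups below 10
samples contribute to the global fit only; a non-positive fitted rate
falls back to the pooled slope with a warning.  Burdens are normalized per
diploid genome (not per gigabase).

**Associations.**  Binary covariates get two-sided rank-sum tests with
Benjamini-Hochberg correction across features; all covariates also enter
one multivariable OLS with 95% CIs.  Constant covariates are dropped.

## Driver ordering

Within a tumor that has a detectable subclone (CCF cluster < 0.8), gene A
precedes gene B when `CCF_A - CCF_B > 0.2`, or when A lies on the upper
side of the clonal peak while B lies on the lower side or in a subclonal
cluster.  "Side" is operationalized as CCF at-or-above versus below the
clonal cluster location; no extra numeric margin is added.  Per-sample
verdicts aggregate into a precedence graph (arc kept when it wins the
head-to-head and covers >= 20% of informative samples); the consensus
ranking minimizes agony, `sum over arcs of max(0, r(u) - r(v) + 1)`,
exactly (exhaustive over compressed ranks) up to 7 nodes and by
coordinate-descent hill climbing with random restarts above.  Stability
comes from 100 bootstrap resamples over patients; arcs recurring in >= 50%
of resamples form the consensus graph.  This is a simplified agony-based
consensus procedure, not a reimplementation of the full ASCETIC model.
Co-occurrence/mutual exclusivity is pairwise Fisher testing (OR > 1
co-occurrence, OR < 1 exclusivity) with BH correction across pairs.

## Signature dynamics

Fold changes use soft attribution probabilities: for signature s,
`p_clonal(s)` is the mean attribution probability over clonal mutations
(early + late + unspecified), `p_subclonal(s)` likewise, and
`FC = p_subclonal / p_clonal`.  Samples without subclonal mutations are
excluded; (sample, signature) cells with clonal attributed mass < 5 are
excluded without pseudo-counts.  The cohort summary reports median FC,
IQR, a signed-rank test of log FC against zero and BH FDR.  The same
operation serves the early-versus-late-clonal contrast via label
arguments.

**ID-83 classification** is a total function on (indel, flanking
context).  1-bp events are typed by the pyrimidine base (A/G complemented
to T/C) and the homopolymer run at the site — including the deleted base
for deletions (classes 1..5, 6+) and the adjoining run only for insertions
(classes 0..4, 5+); consequently the terminal insertion class begins at
run length 5 and the terminal deletion class at 6, the motif boundaries
characteristic of signatures ID1 and ID2.  Longer deletions are classified
by tandem repeat units including the deleted copy (1..5, 6+), falling back
to microhomology length (partial match of the deleted sequence with either
flank), and longer insertions by adjacent existing copies.  Channels total
83.  Flanks shorter than 6 bp leave the indel unclassified with a reason.
Per-signature motif minima take the smallest homopolymer length among
indels attributed to the signature at probability >= 0.5 (the attribution
threshold is a documented choice).

Replication-timing association is a Pearson correlation between
per-chromosome deletion counts and median log2(E/L), requiring >= 3
chromosomes and non-degenerate variance.  Neoantigen propensity is
`1000 * sum P(s|m) I(neoantigenic) / sum P(s|m)` per signature,
suppressed below attributed mass 10.

## Hypoxia score

Per scored gene, the median across tumors defines a +1 (strictly above) /
-1 (strictly below) gene score; exact ties score 0 (the source wording
admits no ties, so the convention is explicit and tested).  The sample
score is the sum over the K genes; with the 286-gene union minus 28
filtered genes, K = 258 and scores span -258..+258.  The removal set is an
input, not hard-coded.

## Synthetic cohorts

The generator is first-class, tested code.  Per sample (one RNG stream per
(seed, sample index), so cohorts extend without reshuffling): purity,
age and latency are uniform in configured ranges (defaults 0.4-0.9,
55-75 y, 8-22 y); whole-genome duplication occurs with probability 0.3 at
molecular time `pi_true` (default 0.3) of the clonal period, otherwise
single-chromosome (2,1) gains occur per chromosome with probability 0.1;
passenger SNVs accrue at a constant per-copy rate (default 3000 per
diploid genome-equivalent) with pre-gain mutations on duplicated alleles
at multiplicity 2; clock mutations accrue at `mu_true` (default 5.0
CpG>TpG per year per diploid genome — a realistic SBS1 scale; the source
study does not state its estimated rate) before the MRCA and `a * mu_true`
after; subclones (default one at CCF 0.4 carrying 30% of passengers) hold
multiplicity-1 mutations, with post-MRCA clock counts scaled by 1/CCF so
the CCF-weighted burden is unbiased for `a * mu * latency`; reads are
Poisson at a copy-number-proportional locus depth (default mean 80) with
binomial alt counts; and a mutation is emitted only when supported by at
least 3 alt reads, mirroring caller detection limits.

That last detection limit is what reproduces the NRPCC power behaviour: at
NRPCC 3 most subclonal mutations are uncalled and the few that survive
have truncated, clonal-looking VAFs, so subclones vanish; at NRPCC 10 the
subclonal cluster survives nearly intact.  Driver mutations follow the
configured gene order (clone assignment is monotone along the order;
an `order_noise` probability reassigns a driver arbitrarily).  Signature
attributions are hard labels from the generating mixture.  Indel contexts
are constructed analytically so the homopolymer/repeat length matches the
requested channel; expression matrices add a configurable shift on the
scored gene block for designated hypoxic samples.

**What the generator does not emulate:** sequencing error and mapping
artifacts, clustered mutational processes (kataegis), nested subclonal
copy number (subclonality is a whole-segment clonal fraction), structural
variants and retrotransposition events, and trinucleotide composition of
the genome (contexts are drawn per signature, not per position).  Passing
tests therefore demonstrate correctness of the inference under the stated
model, not robustness to caller- or mapping-level artifacts in real data.

## Validation scale and numerical choices

The test suite validates: subclone detection power on 100 simulated
samples per depth (3000 mutations each), gain-time recovery on 200
Poisson replicates per state and time-point (checked instance-by-instance
against a 0.001-step grid-search likelihood maximizer), end-to-end latency
recovery on a 100-sample cohort (1500 passenger SNVs per sample; RMSE
within 15% of the mean true latency), agony optimality on 200 random
graphs against exhaustive search, and fold-change calibration on 500 null
cohorts.  EM uses a 1e-4 log-likelihood convergence tolerance and 150
iteration cap; binomial probabilities are clipped to [1e-9, 1-1e-9];
bootstrap CIs use 200 percentile resamples.

## Known limitations

Gain timing covers only (2,1), (2,2), (2,0); subclonal copy number is not
timed; the clock model assumes rate continuity at the MRCA and a single
acceleration factor; the latency estimator presumes the last detectable
subclone arose shortly before diagnosis; consensus ordering is a
simplified agony procedure without ASCETIC's probabilistic model; and
attribution inputs are taken as given (no signature refitting).
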