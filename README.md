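# tumorchrono

Reconstructing the evolutionary chronology of lung adenocarcinoma (or any
tumor cohort) from whole-genome somatic data: when copy-number gains
happened in a tumor's molecular life, how old the tumor's most recent
common ancestor (MRCA) is in calendar years, how long the tumor lay latent
before diagnosis, in what order driver genes were acquired, and how
mutational-signature activity shifted between clonal and subclonal phases.

The package is aimed at cancer-genomics analysts who already have
per-sample somatic SNV/indel calls (VCF with read counts), allele-specific
copy-number segments, and purity/ploidy estimates, and want a tested,
reusable implementation of the downstream evolution analyses — plus a
synthetic cohort generator with full ground truth to validate every stage.

## The models at the core

**Clonal deconvolution.**  A mutation at multiplicity *m* carried by a
cancer-cell fraction CCF in a segment of tumor copy number *n*, at purity
ρ, has expected VAF `m·ρ·CCF / (ρ·n + 2(1−ρ))`.  CCF clusters are fitted
by a binomial-mixture EM with BIC model selection; sample eligibility is
gated on NRPCC = `d·ρ / (ρ·ψ + 2(1−ρ))` > 10 (reads per tumor chromosomal
copy), the quantity that actually governs subclone detection power.

**Gain timing.**  Under a constant per-copy mutation rate, a gain at
molecular time π in a (2,1) segment leaves duplicated/unduplicated clonal
mutation counts with the profile-Poisson MLE `π̂ = 3·n₂/(n₁ + 2·n₂)`
(`2·n₂/(n₁+2·n₂)` for (2,2) and (2,0)).

**Molecular clock.**  CpG>TpG mutations in an NpCpG context accumulate at
μ per year per diploid genome before the MRCA and a·μ after.  With
copy-number and heterogeneity-adjusted burdens B_pre and B_post and age A,

    t_MRCA = A · a·B_pre / (B_post + a·B_pre),    latency = A − t_MRCA.

**Driver ordering.**  Pairwise precedence from CCFs (difference > 0.2, or
opposite sides of the clonal peak) aggregates into a precedence graph;
the consensus order minimizes agony `Σ max(0, r(u) − r(v) + 1)` over 100
bootstrap resamples of patients.

**Signature dynamics and phenotype.**  Per-signature fold change of
subclonal versus clonal attributed proportions; the full ID-83 indel
context classification with homopolymer motif minima (the terminal 1-bp
T-insertion class starts at run length 5, the terminal deletion class at
6 — the ID1/ID2 motifs); and a ±1 median-dichotomization hypoxia score
over 258 genes.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from tumorchrono import (SimConfig, simulate_cohort, time_sample,
                         clock_burden, mrca_and_latency)

config = SimConfig(n_samples=3, seed=1, n_snvs=1500)
cohort, truth = simulate_cohort(config)

sid, data = next(iter(cohort))
st = time_sample(data, seed=0)
print("CCF clusters:", st.clusters.locations.round(3),
      "weights:", st.clusters.weights.round(3))

b_pre, b_post = clock_burden(st.timed, data.segments)
est = mrca_and_latency(sid, data.profile.age_dx, b_pre, b_post, accel=1.0)
print(f"burdens pre/post: {b_pre:.1f}/{b_post:.1f}  "
      f"MRCA age {est.mrca_age:.1f} y  latency {est.latency:.1f} y  "
      f"(true {truth.per_sample.loc[sid, 'latency']:.1f} y)")
```

prints

```
CCF clusters: [0.996 0.396] weights: [0.699 0.301]
burdens pre/post: 313.6/67.9  MRCA age 60.8 y  latency 13.2 y  (true 10.0 y)
```

The two CCF clusters recover the simulated truncal clone (CCF 1.0) and
subclone (CCF 0.4, 30% of mutations).  The adjusted clock burdens —
multiplicity-weighted clonal and CCF-weighted subclonal CpG>TpG counts,
scaled to a diploid genome — convert the 74-year-old patient's counts into
an MRCA age of ~61 years, i.e. roughly 13 years of latency between
subclonal diversification and diagnosis for this sample (Poisson counting
noise puts per-sample estimates within a few years of truth; cohort RMSE
is validated at <15% of mean latency).

The same pipeline is scriptable from the shell:

```bash
tumorchrono simulate --seed 1 --n-samples 10 --out cohort/
tumorchrono time  --cohort cohort/ --out timed/
tumorchrono clock --cohort cohort/ --accel 1 --out clock/
```

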