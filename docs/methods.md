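# Methods

`sowscan` implements a two-track analysis of a repeatedly recorded sow
reproduction trait (number of piglets born alive, NBA): (1) a weighted
single-step genome-wide association study built on ssGBLUP, and (2)
copy-number-variation region (CNVR) inference from per-individual
SNP-array CNV calls, with the two sets of genomic regions intersected at
the end. This note documents the models, the numerical choices, and what
the synthetic data do and do not establish.

## The repeatability animal model

Phenotypes follow

    y = Xb + Wa + K·pe + e

with contemporary group (farm–month–year of farrowing) as the fixed
effect, additive genetic effects `a ~ N(0, A σ²a)` (A the numerator
relationship matrix, including inbreeding), permanent-environment effects
`pe ~ N(0, I σ²pe)` for sows with repeated parities, and residuals
`e ~ N(0, I σ²e)`. Narrow-sense heritability is

    h² = σ²a / (σ²a + σ²pe + σ²e).

The default variance components throughout the package and its simulator
are σ²a = 0.78, σ²pe = 0.57, σ²e = 5.68 (trait units², NBA piglets²),
giving h² ≈ 0.11 — the low-heritability regime typical of litter traits.

### REML estimation

Variance components are estimated by average-information (AI) REML:

- The mixed-model equations are assembled in variance-ratio form with
  λa = σ²e/σ²a on the A⁻¹ block and λpe = σ²e/σ²pe on the pe block.
- The pe block of the coefficient matrix is diagonal and is absorbed
  exactly before factorisation, so each iteration factorises a dense
  system of (fixed + animal) order only. Traces of the full inverse
  needed by the updates are recovered from the reduced inverse
  analytically.
- First derivatives use the standard trace identities; the AI matrix is
  built from working variates (one extra solve per parameter against the
  cached Cholesky factor). An AI step is accepted only if the restricted
  likelihood does not decrease (step-halving otherwise); if no AI step is
  acceptable, the EM-REML update — always uphill — is taken instead.
- Components collapsing to the zero boundary are pinned there (active-set)
  and reported as exactly 0 with a warning; σ²e is never pinned. With no
  pe term in the model (`K=None`, single records), σ²pe is structurally 0.
- Convergence: relative change of all active components < 1e-8 (default)
  or a restricted-likelihood stall (< 1e-9 change), max 200 iterations;
  exhausting them raises an error carrying the full trajectory.
- Standard errors come from the inverse AI matrix; the standard error of
  h² uses the delta method.
- Initialisation: equal thirds of the phenotypic variance — scale-free
  and adequate everywhere we tested.

A dense-V implementation of the restricted likelihood
(`reml_loglik_direct`) exists purely as an independent cross-check; tests
verify that the AI-REML optimum matches a direct Nelder–Mead search on it
to 4+ digits, and that the MME-based likelihood equals the dense-V value
up to the constant term.

## Relationship matrices

- `compute_A`: tabular (recursive) method, vectorised row by row; a
  subset (e.g. A22 for genotyped animals) is cut from the full matrix.
  Desk-scale pedigrees (≤ ~10⁴) only.
- Inbreeding: Meuwissen–Luo algorithm (no A needed), used both for
  pedigree construction and for Henderson's rules.
- `compute_A_inverse`: Henderson's sparse contributions with inbreeding,
  so A·A⁻¹ = I holds for inbred pedigrees.
- `compute_G`: G = Z D Z′ / (2 Σ pᵢ(1−pᵢ)) with Z centred by twice the
  *current* allele frequencies (computed from the genotyped sample — the
  only frequencies available) and D a diagonal SNP-weight matrix
  (identity for unweighted ssGBLUP). Monomorphic SNPs must be removed
  first (`GenotypePanel.drop_monomorphic`); the constructor of G refuses
  them because the centring and denominator are undefined.
- `blend_G`: G ← (1−β)G + β·A22 with β = 0.05 by default, the standard
  guard against singular G. No further compatibility tuning (no mean or
  scale adjustment of G toward A22) is applied.
- `compute_H_inverse`: H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹], dense, with no
  τ/ω scaling of the correction block.

## ssGBLUP

Henderson's MME are solved with the chosen relationship inverse (A⁻¹ for
pedigree BLUP, H⁻¹ for single-step). Below 5,000 equations a dense
Cholesky is used; above, Jacobi-preconditioned conjugate gradients on a
matrix-free operator (sparse design cross-products plus the dense
genotyped-block correction). The relative residual of the solve is
checked against 1e-8. Records of non-genotyped animals are fully
included — genotype status only alters the relationship inverse.
Contemporary-group levels with no records are rejected by a rank check.

## Weighted single-step GWAS

SNP effects are back-solved from the GEBV of genotyped animals:

    û = λ D Z′ G⁻¹ â_g,   λ = 1 / (2 Σ pᵢ(1−pᵢ))

G here is the blended matrix used in the evaluation, so the back-solve is
consistent with the GEBV. λ is recomputed from current allele frequencies
but does not depend on D. Weights are updated as dᵢ = ûᵢ²·2pᵢ(1−pᵢ) and
renormalised so Σdᵢ equals the SNP count (trace of D preserved, keeping
the additive variance scale constant). The iteration is: D = I → build G
→ ssGBLUP → back-solve → reweight → renormalise → repeat. The default is
two iterations (the unweighted pass plus one weighted pass): additional
iterations concentrate weights and mostly overshrink small effects.
Variance components are estimated once, before the loop, and held fixed.

### Window variance

The percentage of additive variance attributed to a window is

    var(Σⱼ zⱼûⱼ) / σ²a × 100,

the *population* variance (divide by n) of the window genetic value
across genotyped animals. Windows slide per SNP: one window starts at
every SNP and contains all subsequent SNPs within 1 Mb of the start, so a
reported window's span is the distance between its actual first and last
SNP (< 1 Mb). `select_significant_windows` keeps windows above the
threshold (default 1% of σ²a) and collapses mutually overlapping
survivors to the local maximum, so one QTL region is reported once.
Because window variance is computed from centred genotypes, it is
invariant to shifting any SNP's coding by a constant.

## CNV region inference

Per-sample QC is strict on every threshold: call rate > 0.98, call
frequency > 0.90, and — when signal metrics are available — BAF drift
< 0.01, LRR SD < 0.30, GC wave factor < 0.05; a sample missing signal
metrics is not failed on their account. Calls spanning fewer than three
consecutive SNPs are discarded. Overlapping calls (≥ 1 bp, transitive
closure, same chromosome) are concatenated into CNVRs whose span is the
union of member intervals — this is what resolves inconsistent boundary
calling. Region filters: at least two distinct carrier samples (the
"seen in more than one animal" rule is enforced at region level, where it
is assessable), carrier frequency ≥ 0.5% of QC-passed samples (carriers
counted once per sample), and recurrence ≥ 0.1. Recurrence is defined
here as the mean over member calls of (call length / region length) — a
(0,1] overlap density that is small when a region is inflated by a few
long outlier calls. The field uses "recurrence" loosely and no canonical
formula exists, so the definition and the threshold are configurable.
The loss:gain ratio counts mixed-state ("both") regions on both sides:
(n_loss + n_both)/(n_gain + n_both). Coordinates are 1-based inclusive
internally (the rawcnv convention); BED export converts to 0-based
half-open at the writer only.

## GWAS × CNVR integration

Every (significant window, CNVR) pair sharing at least 1 bp is reported
with its overlap length and the CNVR state; no minimum overlap is imposed
— the lengths let users filter. Gene annotation is a generic interval
join against a user-supplied gene table; no ontology analysis is done.

## Synthetic data

The generator emulates the data structure of a commercial Duroc
population at desk scale:

- Discrete-generation pedigree (default 200 founders + 4 × 1,000), sexes
  alternating within cohorts, random mating from the previous generation.
- Genotypes by gene-dropping: founder haplotypes Bernoulli at per-SNP
  frequencies uniform on [0.05, 0.5]; offspring inherit one allele per
  parent per locus independently. There is therefore **no linkage
  disequilibrium beyond co-ancestry**: a QTL is tagged only by itself.
  Default map: 5,000 SNPs over 18 autosomes of 10 Mb each (≈ 28 SNPs per
  1-Mb window) — a deliberately compressed genome that keeps window
  analyses meaningful at desk scale.
- The genotyped subset is the most recent 95% of sows, matching a sow
  SNP panel in which the genotyped animals are the phenotyped ones
  (configurable via `genotype_females_only` / `genotyped_fraction`).
- Phenotypes come from exactly the repeatability model above; only
  females receive records (1–12 parities by default; contemporary-group
  means N(10.5, 1) on the NBA scale across 9 groups). Optionally, part of
  σ²a (default 40% when QTL are requested) is assigned to `n_qtl` planted
  QTL with equal absolute effects and random signs, rescaled so the
  realised QTL variance among all pedigree animals matches the requested
  fraction exactly; the polygenic remainder follows the pedigree
  recursion with inbreeding-adjusted Mendelian sampling variance.
- CNV calls: latent regions of 6 consecutive SNPs placed on the map,
  loss:gain odds 8.4 (the loss excess SNP-array callers report in pigs),
  carrier frequencies uniform on [0.01, 0.3]; each carrier emits one call
  with endpoints jittered uniformly by up to ±2 map positions — the
  boundary inconsistency the CNVR concatenation step exists to absorb.
- All randomness flows from a single seed through named sub-streams
  (pedigree / genotypes / phenotypes / cnv / qc), so each component is
  independently reproducible and identical configurations give
  byte-identical outputs.

What passing the synthetic benchmarks shows — and what it does not: the
generator contains no LD structure, no selection, no non-additive
effects, and its genome is length-compressed; recovery results therefore
validate the estimation and bookkeeping machinery under the model's own
assumptions, not robustness to the messiness of real SNP-array data.

## Benchmark problem sizes

The recovery experiments (`sowscan.experiments`) use: REML — 4,200
pedigree animals, ~2,100 sows with 3–6 records each; WssGWAS — ~2,000
genotyped sows, 5,000 SNPs, 5 QTL carrying 40% of σ²a, 20 replicates in
the test suite (fewer in the reproduction script); CNVR — 60 latent
regions over ~2,000 samples. At ~2,100 sows the AI standard errors of
σ²a and σ²pe are ≈ 0.09–0.11 — about 15% of the generating values — so
single-seed estimates scatter by design; the REML benchmark therefore
aggregates five fixed seeds and judges the seed-averaged components
(a ~1.7-SE test of unbiasedness), while h², whose standard error is much
smaller (≈ 0.017), is checked per seed. Replicate counts were fixed by
this power computation.

## Known limitations

- Dense factorisations bound pedigrees to desk scale (~10⁴ animals).
- No metafounders, unknown-parent groups, or APY-style sparse G.
- Single-trait models only; no maternal effects.
- The PennCNV caller itself, LRR/BAF extraction and GC-wave modelling are
  upstream of this package: it consumes rawcnv-style calls and per-sample
  QC metrics, it does not produce them.
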