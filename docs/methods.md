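# Methods

This note documents the statistical machinery of `mbfish`: the models,
the test backends, the search semantics, the synthetic-data generator,
and the design decisions taken where the procedure was genuinely open.

## Markov-blanket selection by repeated fishing

### Target of inference

For a phenotype Y and markers X = {x₁, …, x_p}, the Markov blanket
MB(Y) is the minimal set with V ⊥ Y | MB(Y) for all V ∈ X − MB(Y).
Under a causal-diagram view in which disease never causes genotype,
MB(Y) is the set of directly phenotype-related markers; everything
else — in particular LD neighbours of causal SNPs — is conditionally
independent of Y given the blanket. Selecting MB(Y) therefore promises
both fewer false positives than penalized regression and sharper
localization than marginal testing.

### Conditional-independence backends

* **`g2`** (categorical markers, categorical phenotype): the
  likelihood-ratio statistic G² = 2 Σ O ln(O/E) over the Y × V table,
  stratified by the joint levels of the conditioning markers and summed
  across strata, referred to χ² with df =
  (Cat(Y)−1)(Cat(V)−1)·∏Cat(Cᵢ). Conventions: O ln(O/E) := 0 for O = 0;
  rows/columns with a zero margin (and entirely empty strata) are
  dropped with their df contribution subtracted. If more than 20 % of
  the full table's cells have expected count < 1 the test is flagged
  *unreliable*; callers treat an unreliable test as uninformative and
  never as evidence of dependence — the conservative direction.
* **`logistic` / `linear`** (quantitative markers and/or phenotype):
  Wald test (squared z, df 1) of the target's coefficient in a
  logistic/OLS model that enters the conditioning set as covariates.
  Rank-deficient designs, separation and non-convergence produce an
  unreliable no-test result instead of an exception.

Marginal screening uses the Cochran–Armitage trend test (scores 0/1/2)
for SNP dosages against a binary phenotype — the genotypic 2×3 G² is
available as an option — and the regression test otherwise. Screening
level: 0.05 by default (a 0.01 preset suits genome-scale data).

### Why first-order conditioning

Conditioning on the whole blanket multiplies table cells by three per
ternary SNP admitted; at nine conditioners the table has 118,098 cells
and the test is powerless at any realistic n. The search therefore
tests a candidate against **each single blanket member separately** and
summarizes with the *worst-case* (largest) p-value: a candidate is
dependent only if every single-conditioner test rejects at α. With at
most one conditioner, no table exceeds Cat(Y)·Cat(V)·Cat(C) cells.

### One fishing round

Candidates are ranked by marginal p-value. Each forward step examines
only the top-ranked remaining candidate: if it is dependent (worst-case
first-order p < α, default α = 0.05) it joins the blanket, otherwise
the forward phase ends. This stop-at-first-failure convention is the
classic grow-shrink/DASSO forward loop (the top-scoring variable
failing its test terminates the phase); the alternative reading —
scan the whole pool each step and admit the best passing candidate —
turns out to admit a near-unbounded stream of just-under-threshold
noise markers, because the minimum of ~50 correlated near-threshold
p-values almost always clears α, and was rejected for that reason.

After each admission:

* **LD pruning**: pool markers whose position index lies within 20
  markers of the admitted SNP *and* whose genotype r² with it exceeds
  0.05 are removed from the pool (both conditions required; the window
  is counted in marker-index units). A captured LD block thus
  contributes one representative.
* **Backward pruning**: members are re-tested (first-order, against the
  other members), most-recently-admitted first, and removed while
  unsupported; the pass repeats until stable, so it is idempotent.
  Removed members are discarded permanently rather than returned to the
  pool — returning them could re-admit and re-remove forever.

### The repeated-fishing loop

Round k+1 fishes the pool left over from round k (members and LD
casualties removed). Because the new blanket starts empty, a weak true
signal that kept failing conditional tests behind strong members in
round k is examined *marginally* at the top of round k+1 — this is
where the strategy recovers the false negatives of a single blanket.
The loop stops at the first round returning ≤ `stop_size` (default 2)
members, at an empty blanket or an empty pool; a 50-round cap guards
pathological inputs. The terminal small round **is** included in the
final set by default (`include_terminal_round=True`): excluding it
would return nothing when exactly two true signals exist; under the
null it contributes the one-or-two chance markers that dominate the
(tiny) null selection rate.

### Legacy single-blanket mode

`run_single_mb_baseline` runs exactly one round with **full**
conditioning on all current members — the behaviour the fishing
strategy was designed to fix. Tests whose projected table exceeds
`max_cells` (default 10⁵, i.e. about eight ternary conditioners) are
refused and treated as uninformative, making the empty-cell pathology
explicit rather than silent.

## Comparison methods

* Trend test + Bonferroni (p < α/m) and + Benjamini–Hochberg step-up
  (statsmodels implementation), fed by the identical trend p-values
  used elsewhere in the package.
* L1-penalized logistic regression on standardized dosages; the penalty
  is chosen by 10-fold cross-validated log-loss with the
  one-standard-error rule (strongest penalty within one SE of the best
  mean loss), with a fixed-penalty override. The original comparison
  did not state its LASSO tuning, so no benchmark number is pinned to
  it here.

## Synthetic data

The generator replaces a HapMap-resampling pipeline with a parametric,
seedable construction.

* **Genotypes.** Each individual is the sum of two independent latent-
  Gaussian haplotypes; allele j is "minor" when its latent variable
  falls below Φ⁻¹(MAF_j), so Hardy–Weinberg holds by construction and
  genotype correlation equals allele correlation. Within a region the
  latent correlation implements the declared LD regime — *high* and
  *modest* regions are exchangeable blocks (every pair at the target
  r², like a tight haplotype block; target r² 0.90 and 0.45), *low*
  regions are AR(1)-style chains (adjacent r² 0.10, decaying with
  distance), and an explicit `ar1(ρ)` profile exposes the chain
  directly. The latent correlation for a target genotype r is obtained
  by inverting the bivariate-normal orthant probability (Owen's-T
  formula, Brent root-finding) at the pair's MAFs — exact calibration,
  no simulation tuning. High/modest regions share one MAF (strongly
  mismatched allele frequencies cap attainable r² far below the regime
  targets); other profiles draw per-marker MAFs from the region's
  range, quantized to 10⁻³ so the calibration cache is effective.
* **Genome layout.** 22 regions × 50 SNPs = 1100 markers by default,
  cycling low/modest/high profiles with MAFs in (0.05, 0.5) — a
  miniature genome with varied LD and allele-frequency structure.
* **Phenotype.** Logistic disease model P(Y=1|G) =
  expit(α₀ + Σ log(OR_j)·G_j) over the causal dosages; α₀ is solved
  numerically so the population prevalence equals 0.10 (a conventional
  choice; configurable). Case-control studies draw exactly n_cases /
  n_controls without replacement from the simulated population and
  fail loudly, naming the deficit, if the population cannot supply
  them.
* **Scenarios.** (1) 8 causal SNPs generated independently of all
  background SNPs, each replacing one background column in a distinct
  region (LD-free causal markers, marker count preserved); (2) as (1)
  but the causal SNPs are pairwise correlated via an exchangeable
  latent copula calibrated so their *genotype* correlation is ≈ 0.1;
  (3) causal SNPs are in-block members sharing their region's LD; (4)
  three regions (high/modest/low LD), one causal SNP each at OR 1.5.
  Effect-size schemes: all-null (OR 1), the OR ladder 1.1…1.8 at MAF
  0.3, fixed OR 1.3 with MAFs spread over 0.05…0.5, and uniform OR 1.2.
* **What it does not emulate.** Real LD is block-*and*-decay with
  recombination hotspots and allele-frequency-dependent structure; the
  generator's regimes are stylized (pure exchangeable or pure chain).
  Genotyping error, missingness, population stratification and
  covariates are absent. Passing benchmarks here shows the selector's
  operating characteristics under clean LD and a correctly specified
  logistic model — not robustness to the artefacts of real cohorts.

A note on the correlated-causal condition: applying the stated 0.1
correlation on the genotype scale hands each causal SNP a marginal
log-odds boost of ≈ 0.1 × Σ (other log-ORs), i.e. the weakest SNP
behaves marginally like OR ≈ 1.45, which pushes single-marker
Bonferroni power essentially to one. An alternative latent-scale
reading (realized genotype correlation ≈ 0.06) gives visibly lower
marginal power. The genotype-scale calibration is the stated constraint
and is what the package implements; the consequence for the
single-marker baseline is documented rather than recalibrated away.

## Evaluation

Per replicate: TP/FP/FN/TN over the marker set, TDR = TP/(TP+FN),
FDR = FP/(TP+FP) with 0/0 → 0, and MCC =
(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) with any zero factor
→ 0. Replicate aggregation is the arithmetic mean of per-replicate
metrics (the 0/0 conventions applied locally). For causal SNPs inside
LD blocks, cluster scoring replaces marker counts: every captured SNP
within 20 positions and r² > 0.05 of a true SNP folds into one
true-positive cluster per true SNP; remaining captures chain into
false-positive clusters when ≤ 10 positions apart; cluster-level TN is
approximated as markers participating in no cluster. Per-marker
discovery rates are percentages of replicates selecting the marker.

## Problem sizes and determinism

The shipped benchmarks run 1000 cases / 1000 controls over 1100 SNPs
drawn from populations of 20,000 at 60–200 replicates — large enough
that the replicate-averaged TDR/FDR/MCC are stable to a few points
(binomial SE ≈ 0.015 at 100 replicates) while a full benchmark stays in
the minutes range on one CPU. `ScenarioSpec.population_size` defaults
to 100,000 for users who want the original population scale. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical specs produce bit-identical
datasets and identical selections.

## Known limitations

* First-order conditioning can in principle admit a marker that is
  independent of Y only given *pairs* of blanket members; such
  structures (e.g. pure epistasis masking) are outside the selector's
  reach by design.
* The stop-at-first-failure forward phase makes admission order — and
  occasionally membership — depend on the marginal ranking; ties are
  broken deterministically by marker index.
* Cluster-level TN (and hence cluster MCC) is an index-unit
  approximation.
* The LD-pruning window counts markers, not base pairs; on real data
  the marker order of the input file defines adjacency.
* The LASSO baseline's tuning convention materially affects its
  selection rate; treat its numbers as indicative only.
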