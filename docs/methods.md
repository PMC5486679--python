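# Methods

This note records the models, conventions and numerical choices behind
`ldne`, and what the synthetic-data tests do and do not demonstrate about
real chip data.

## Pairwise r² by EM

Genotypes are allele-B dosage codes (0/1/2, −1 missing). For a SNP pair the
3×3 genotype count table is built from pairwise-complete individuals, so the
per-pair sample size `n_used` varies with missingness. Under random union of
gametes every cell determines its two haplotypes except the double
heterozygote, which contributes one coupling (A1B1/A2B2) or one repulsion
(A1B2/A2B1) pair. EM splits the double-het count by the expected coupling
fraction w = p₁₁p₂₂/(p₁₁p₂₂ + p₁₂p₂₁) and re-normalizes; convergence is
declared when the largest frequency change falls below 1e-10, with a
1000-iteration cap.

The observed-data likelihood is multimodal whenever double heterozygotes
dominate: for a table containing only double heterozygotes the maxima are
the two fully-phased solutions (r² = 1, D = ±¼) and the linkage-equilibrium
point D = 0 is a saddle. A single EM start can therefore converge to a local
optimum; we observed this on an ordinary random table of 7 individuals, not
just in the degenerate case. EM consequently runs from three deterministic
starts — the linkage-equilibrium product and the two ends of the feasible
p₁₁ interval — and returns the fixed point with the highest likelihood.
Determinism is preserved (no random restarts); exact ties go to the
linkage-equilibrium start. Note the consequence for fully ambiguous tables:
the estimator returns the maximum-likelihood r² = 1, not the agnostic 0.
Such tables essentially never arise from real chip loci, which is why the
MLE contract was kept.

r² = D²/(p_A1 p_A2 p_B1 p_B2) with D = p₁₁p₂₂ − p₁₂p₂₁, clipped to [0, 1]
against floating-point rounding. Pairs monomorphic among the individuals
used are skipped and counted, not errored. The EM likelihood is checked in
tests against a grid search; because the genotype likelihood's marginals
force the allele frequencies to their observed values, the grid profiles the
haplotype simplex down to the one-dimensional feasible interval of p₁₁
(10⁻³ step), backed by a coarse full-simplex sweep.

## Binning and the decay curve

Canonical bin edges are 0, 10 kb, 25 kb, 50 kb, 100 kb, 500 kb, 1 Mb, 5 Mb,
10 Mb, and a pair belongs to the unique bin with lower < d ≤ upper (a pair
at exactly 10 kb is in the first bin). Only within-chromosome pairs up to
10 Mb are evaluated — beyond that recombination is effectively free and the
pairs carry no drift signal. No window SNP cap and no r² floor are applied.
Per bin we report the arithmetic mean, SD and SE of r² plus the pair count;
genome-wide summaries are the pair-count-weighted pool of the
per-chromosome accumulators, so the two scopes are consistent by
construction. Binning is streaming (running sums); pair-level output never
needs to fit in memory.

## Sved inversion and the time axis

Physical distance converts to genetic distance at 1 cM/Mb by default
(100 kb ≈ 0.1 cM), configurable via `cm_per_mb`. Each bin's c is taken from
its **upper** edge — the convention that pairs the 10–25 kb bin with
c = 0.00025 and t = 1/(2c) = 2000 generations. This choice affects every
estimate: within a wide bin most pairs sit at distances below the upper
edge, where expected r² is higher, so inverting the bin's arithmetic mean
r² at the upper-edge c biases Nₑ downward, increasingly so for the wide
1–5 Mb bin (observed ratio ≈ 0.5 of truth in simulation). Conversely,
sparse short-distance bins are noisy and upward-biased. The alternative
(harmonic-mean or midpoint c) is deliberately not offered; the upper-edge
convention matches the generation grid the decay tables are reported on.

`expected_r2(ne, c, n, k=4, alpha=2)` evaluates E(r²) = 1/(α + kNₑc) + 1/n;
`ne_from_r2` inverts it and returns NaN (a flag, not an exception) when
r² ≤ 1/n, where drift is indistinguishable from sampling noise. α defaults
to 2 to match the inversion formula's printed constant; both α and k are
exposed. n is the diploid individual count; a flag switches the sampling
term to 2n chromosomes for sensitivity analysis. The round-trip
`ne_from_r2(expected_r2(Nₑ))` = Nₑ is exact to 1e-6 over a wide grid and is
the primary correctness anchor, because published trajectory tables for
real cohorts cannot be regenerated without the underlying genotypes.

## Marker QC

Filters run in the order call rate (≥ 0.95), MAF (≥ 0.05), HWE (p > 1e-5),
each on the survivors of the previous step — but all three statistics are
computed once on the input matrix and never recomputed between steps, so
the surviving set is order-independent while per-step removal counts follow
the stated order. Individuals are never filtered. The HWE test is the exact
conditional test: given n diploids and the rarer allele count, the
heterozygote count h has probability proportional to
n!/(n_hom_rare! h! n_hom_common!)·2^h; the two-sided p sums all h whose
probability is ≤ the observed one (ties included, plain p rather than
mid-p — conservative and conventional). Weights are exact integers, so tie
comparison involves no rounding. A chi-square variant is available behind
`hwe_method="chisq"`.

## Diversity

H_E is the mean of 2p(1−p) over loci; P_N is the fraction of loci with
MAF ≥ a threshold (default 0.05 — P_N has no universal definition, so the
threshold is exposed). Per-individual F uses uncorrected excess
homozygosity over that individual's called, informative (0 < p < 1) loci;
a `unbiased=True` flag applies the small-sample 2n/(2n−1) factor to the
heterozygosity term, as common QC tools do. The uncorrected form is the
default for transparency.

## Synthetic panels

The generator's default engine is the msprime coalescent with
recombination: one tree sequence per chromosome, binary mutations at a rate
auto-chosen from Watterson's expectation to oversupply the SNP target
about five-fold, diploid individuals formed from consecutive sample
haplotypes. Sites below `maf_floor` (sample MAF) are dropped — a crude
stand-in for chip ascertainment — then sites are thinned uniformly at
random (seeded) to the per-chromosome target; a shortfall raises an error
naming the deficit. Piecewise-constant Nₑ epochs are supported. A pure
forward Wright–Fisher engine (standing variation at frequency ½, ≥ 4Nₑ
burn-in generations, per-interval Haldane recombination, no mutation,
constant Nₑ only) exists for degenerate regimes — zero recombination, tiny
populations — where an explicit population is easier to reason about.
Identical config and seed give bit-identical output on both engines; all
per-chromosome and missingness streams derive from one `SeedSequence`.

What the generator does **not** emulate: real ascertainment (chip SNP
selection against a discovery panel), mutation-rate and recombination-rate
heterogeneity, selection, migration, non-random mating, genotyping error
structure beyond uniform missingness, and the X chromosome. Passing
recovery tests therefore show that the estimator chain is internally
consistent under neutral-drift LD, not that its point estimates are
unbiased for any particular livestock cohort.

**Accuracy of Sved's relationship.** Sved's E(r²) = 1/(2 + 4Nₑc) + 1/n is
an approximation, and the package treats it as such. A dedicated two-locus
replicate experiment (`replicate_pair_r2`: the exact Wright–Fisher Markov
chain on four haplotype counts, 4Nₑ burn-in generations, hypergeometric
sampling of n diploids, EM r², replicates discarded when a locus falls
below the MAF floor) shows mean r² at Nₑ = 500, c = 0.001 of ≈ 0.35–0.39
against the formula's 0.255: conditioning on segregation after long drift
retains old, tightly correlated allele pairs, inflating r² at small 4Nₑc.
A coalescent version of the same experiment gives ≈ 0.35. Tests therefore
hold the generator to the formula within a factor of 2 on the drift term,
the same band used for trajectory recovery — not to Monte-Carlo precision.

**Recovery benchmark.** Panels of 2 chromosomes × 25 Mb × 800 SNPs
(≈ 31 kb spacing — denser than a 50K chip's ≈ 57 kb so that several bins
accumulate ≥ 2000 pairs at this scale), n = 200 individuals, MAF floor
0.05, true constant Nₑ ∈ {200, 1000}. Bins holding ≥ 2000 pairs recover Nₑ
within a factor of 2 in ≥ 80% of cases (observed 90%); the structural
misses are the short-distance bins (upward bias, few pairs — excluded by
the pair threshold) and the wide 1–5 Mb bin (downward bias from the
upper-edge convention, discussed above).

## Pipeline and experiment

`run_pipeline` reads a TOML config, runs input → map summary → QC → LD →
Nₑ → diversity → optional subsampling, writes TSVs with headers plus a run
log (package version, parameter echo, stage summaries — no timestamps), and
is byte-reproducible for a fixed seed. A stage failure removes the output
directory and raises an error naming the stage.

The subsampling experiment draws individual subsets without replacement
(per-size child seeds of one `SeedSequence`), reuses the full-panel QC SNP
set — re-running MAF-driven QC per subset would change the marker set with
sample size and confound the comparison — and records each subset's mean r²
over 0–50 kb. Subset means are compared by classical one-way ANOVA with
Fisher's LSD pairwise t tests at α = 0.05 (pooled within-group mean
square), with compact-letter grouping of the means; replicates are the
pair-level r² values in the 0–50 kb window. The 1/n term makes short-range
mean r² decrease with sample size in expectation, which is the property the
tests check.

## Known limitations

- Nₑ estimates carry no confidence intervals; the bin SE describes r²
  dispersion, not Nₑ uncertainty.
- Present-day Nₑ is out of scope (no correction for the most recent
  generations; the trajectory's closest point is t = 5 at 10 Mb).
- The EM is exact only under random mating (Hardy–Weinberg within loci);
  inbred panels violate its phase model.
- D′, haplotype blocks, LD pruning and gene-annotation of high-LD regions
  are deliberately not implemented.
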