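# Methods

This note records the models behind each pipeline stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
known limitations. Coordinates are 1-based inclusive throughout; one master
seed drives every simulator through named substreams, so adding a simulator
never perturbs existing streams and identical configurations are
byte-reproducible.

## Genome model

All desk-scale analyses run on a miniature genome of four 100-Mb metacentric
chromosomes (centromere at 50 Mb). Nothing in the copy-number or scar
arithmetic depends on chromosome sizes — only on arm boundaries — so results
transfer to real coordinates; a packaged GRCh37 arm table
(`carcinoscope/data/hg19_arms.tsv`, autosomes + X with centromere midpoints)
is loadable via `hg19_genome()`.

## Synthetic cohorts (simcohort)

Two components per tumor share a clonal trunk: each SNV is independently
trunk with probability `shared_event_fraction` (default 0.6); private
mutations split evenly between components and sit in subclones at CCF 0.6 /
0.5. Channels are drawn from the mixture `W · e` of reference signatures, so
catalog construction and deconvolution can be tested against the planted
exposure simplex. The read model is binomial at Poisson-distributed depth
(default 77x, the tumor coverage regime the pipeline targets); depth affects
only noise, never expectations.

Segment profiles plant exactly `n_lst_events` qualifying large-scale breaks
(both flanks ≥ 10 Mb after 3 Mb smoothing). Arm states cycle through three
genotypes — the ploidy-balanced base, a single-copy gain, and a full-LOH
loss. The LOH state is essential, not decorative: a genome whose minor copy
number is ≥ 1 everywhere is *exactly* aliased under "subtract one copy of
each allele and add normal contamination", so purity and ploidy would be
unidentifiable in principle; an LOH segment pins purity through its BAF of
`(1 + p)/2`, as it does in real aneuploid tumors. Binned read counts carry a
multiplicative GC bias (independent per-bin GC plus a weak long-range wave so
the two correction windows see distinct scales) and Poisson noise; het sites
every 25 kb with binomially sampled BAF.

Kataegis clusters are planted as 8 TpC C>T/C>G mutations inside 2 kb, 1–10 kb
from a breakpoint of the sample's SV table, sharing a VAF and a clone label
(one burst arises in one population). Tandem duplications are dispersed
proportionally to chromosome length with log-normal spans around 10 kb — the
tandem-duplicator regime. Microsatellite tables give each site a tight
normal-sample length distribution; unstable sites shift the tumor mode down
by 3 repeat units and double the spread.

What the generator does *not* emulate: read-level artifacts (mapping error,
strand bias, FFPE damage), subclonal copy number within one sample,
mutation-rate variation along the genome, germline contamination of somatic
calls, and replication-timing covariates. Green tests therefore demonstrate
correctness of the inference logic under the stated forward model, not
robustness to every artifact of real sequencing.

## Copy-number inference (genomeprofile)

**GC correction.** Raw counts are divided by two multiplicative components
fitted by backfitting (three rounds, since the two GC tracks are correlated):
a lowess smooth on per-bin GC (frac 0.3) and a *linear* term on GC averaged
over 5 neighboring bins (500 kb at the default 100-kb bins). The long-scale
term is kept linear deliberately: a flexible smoother at that scale can
absorb genuine copy-number structure and attenuate the CN contrast the later
stages depend on. Corrected counts are normalized to mean 1. Constant GC
degrades to an identity correction with a warning; fewer than 200 bins is an
error.

**Purity / mean ploidy.** Bins are first summarized into homogeneous blocks:
block boundaries follow jumps of a 9-bin rolling median (threshold = median
jump + 8 robust SDs, so it adapts to noise), blocks are capped at 100 bins,
and each block contributes its median read count, a folded-BAF estimate
pooled over all its het sites, and a weight down-scaled by its internal
spread (blocks straddling an undetected breakpoint are unreliable for every
candidate model). Folded BAF uses the noise-corrected estimator
`fa = 0.5 + sqrt(max(0, mean((b−0.5)²) − mean(b(1−b)/d)))` because naive
folding biases balanced regions upward. The grid (purity 0.05–1.00 step 0.01
× ploidy 1.5–6.0 step 0.05) scores each candidate by inverting the block
centers to implied total and major copy numbers and measuring squared
distance to the nearest valid integer state. Scoring in copy-number space —
not signal space — makes the score diverge as purity → 0 and removes the
classic low-purity degeneracy. Near-ties (within 1 % relative) prefer the
lower ploidy, then the higher purity: a conservative resolution of the
genome-doubling alias. Flat signals (no CN contrast, BAF ≈ 0.5 everywhere)
return an explicit `unidentifiable` status.

Verified performance on the 20-sample synthetic design (purity 0.3–1.0,
ploidy 2–5): median purity error 0.00, ploidy within 0.3 in 19/20.
*Limitation:* below ~0.2 purity the CN contrast (≈ 1 % in relative read
count) sits inside the GC-calibration ripple and is amplified by 1/p in
copy-number space, so the estimate is not trustworthy there; sample QC is
expected to consume an external (array-derived) purity for such samples, and
discards anything under 20 %.

**Segmentation.** A hidden Markov model whose states are all genotypes
(major, minor) with total ≤ 8. Emissions are Gaussian: read count around the
lattice mean (SD from the median absolute successive difference, floor 1e-3)
and per-bin folded BAF around the genotype mean (SD shrunk by the het count;
bins without hets contribute the read-count term only, and chromosomes
without any het site are flagged genotype-unknown). Transitions stay with
probability 1 − 1e-5 per bin. The Viterbi path is decoded per chromosome —
with a uniform off-diagonal transition matrix the best predecessor is either
the same state or the single best other state, so decoding is O(bins ×
states). Runs of identical state merge into segments. On noiseless input the
planted breakpoints are recovered to ± 1 bin.

**Summaries.** FGA is the length fraction with total CN different from the
length-weighted modal ploidy. Breakpoints are genotype changes between
adjacent same-chromosome segments (a flag switches to total-CN changes);
chromosome ends contribute nothing. SV classes follow discordant-pair
orientation conventions — (+,−) deletion-type, (−,+) duplication-type,
(+,+)/(−,−) inversion-type after ordering breakpoints by position,
cross-chromosome pairs are translocations; this mapping is a documented
convention, not asserted from any external source. Broken genes require a
breakpoint inside the gene and strictly more than 15 supporting reads.

## Mutational signatures (mutsig)

Catalogs use the canonical 96 pyrimidine-normalized trinucleotide channels in
COSMIC order. Deconvolution minimizes generalized Kullback–Leibler divergence
(sklearn NMF, multiplicative updates), 10 random restarts per fit with the
best kept. Each Monte-Carlo bootstrap multinomially resamples every sample's
counts and refits; bootstrap signatures are matched to the first run by
greedy cosine pairing (a documented simplification of optimal assignment —
adequate because matched clusters are tight whenever the rank is stable), and
the reported signature is the per-channel mean over bootstraps, after which
exposures are refit on the original catalog with the averaged signatures
fixed (multiplicative KL updates for H only). Per-signature stability is the
mean silhouette of the matched bootstrap signatures under 1 − cosine
distance.

Rank selection scans k = 2..10 and keeps the largest k whose mean silhouette
is ≥ 0.80 *and* whose relative residual (Frobenius) improvement over k − 1 is
≥ 5 %. Both thresholds are configurable; they operationalize "stable
clustering of bootstrap signatures" and "minimal residual weight", which the
method family names without numbers. If no rank qualifies the most cohesive
one is returned flagged unstable (the pure-noise behavior).

Reference matching reports the best-cosine label per signature plus a joint
Ward clustering (1 − cosine) of fitted and reference profiles. The packaged
reference is a *synthetic* catalog in the COSMIC v2 layout (96 × 11) whose
members reproduce the family structure matching relies on — clock-like
C>T@NpCpG (1), APOBEC TpC (2/13), flat BRCAness (3), the MSI group
(6/15/20/26) and broad fillers (5/8/17); shapes are parametric caricatures,
not the measured profiles, and real-data use should load the real catalog
TSV. Per-mutation assignment is the posterior `W[c,j]H[j,s]` normalized over
j; ties break to the lower index and are flagged, zero-weight channels are
`unassigned`.

Note that NMF is only identifiable up to mixing when no sample anchors a
signature; the exact-recovery test plants pure-exposure anchor samples for
this reason.

## Genomic scars (scars)

Smoothing removes copy-number variations strictly shorter than 3 Mb,
iterating to a fixpoint (neighbors sharing a state merge; otherwise the short
segment joins its longer neighbor), which makes the operation idempotent. LST
counting then works per arm on runs of constant total CN: a break counts iff
both flanking runs span ≥ 10 Mb inside the arm, so centromere-crossing breaks
never count. Total-CN (not genotype) change defines the break, matching the
original large-scale-transition literature; > 20 LSTs raises the BRCAness
surrogate flag, and HRD status is high iff BRCA1/2 is altered or LST > 16,
low iff wild-type and LST < 6, intermediary otherwise. Promoter
hypermethylation counts as a BRCA alteration by default (toggleable) — the
underlying biology (epigenetic silencing phenocopies mutation) argues for it,
but the classification sentence does not settle it.

The TDP score is `c₀ − Σ_chrom |obs − exp| / N` over intra-chromosomal
duplications with expected counts proportional to chromosome length;
`c₀ = 0.71` (the Menghi constant) is configuration, not a claim of this
package. The flag additionally requires the kernel-density mode of log10
span to fall in 1–100 kb.

MSI: per site, a Pearson chi-squared homogeneity test (no continuity
correction) on the tumor vs normal length histograms, pooling adjacent rare
length bins until expected counts reach 5; sites under 20 reads in either
sample are excluded; a site is unstable at p < 0.05 and the tumor is MSI iff
the unstable fraction strictly exceeds 20 %. Null calibration was verified at
the test level (± 2 % over 1,000 sites).

Kataegis requires all four criteria jointly: (i) a maximal run of ≥ 6
mutations whose mean distance to their 5 nearest neighbors is ≤ 1 kb, (ii)
≥ 80 % of the cluster at C>A/C>G/C>T in a TpC context, (iii) VAF spread
≤ 0.15 or a shared clone label, (iv) a rearrangement breakpoint within 50 kb.
None of these constants come from the source method description (which names
the criteria only); all are configurable, and the defaults achieve
sensitivity ≥ 0.9 with zero false events on the 50-replicate planted design.
With no SV table criterion (iv) is unsatisfiable and all candidates are
rejected with a warning.

## Clonal reconstruction (clonal)

The CCF transform is `ccf = vaf (p·cn + 2(1−p)) / (p·m)` with multiplicity
`m = round(vaf (p·cn + 2(1−p)) / p)` clipped to [1, major]; values clip to
[0, 1.2] with an overflow flag. Paired-component clustering is a binomial
mixture over CCF pairs: cluster c has a CCF per sample, the likelihood of a
mutation is the product of binomials at expected VAF `ccf · q` (q the
CCF-to-VAF factor), and EM uses a method-of-moments CCF update (the exact
M-step has no closed form once q varies per mutation). Component count by BIC
over k = 1..8, 10 restarts, fixed seed. The cluster nearest CCF (1, 1)
becomes the clonal population C1; other clones attach to the most specific
placed node that dominates them per sample (tolerance 0.05) and has remaining
child capacity — a greedy pigeonhole rule. Under 50 mutations a flagged
single-clone fallback is returned. This whole stage is an explicitly
simplified stand-in for multi-population CNA + MCMC tree inference, which is
out of scope; it recovers the planted 3-clone design at ≥ 90 % assignment
accuracy.

Shared events between components: SNVs/indels match on (chrom, pos, ref,
alt); CNA segments on identical genotype with reciprocal overlap ≥ 0.5; SVs
when both breakpoints agree within ± 1 kb (matching rules are package
choices; the source reports cohort percentages without defining its
denominator, so both Jaccard and per-sample fractions are emitted and no
claim is made to reproduce those cohort numbers).

Genome-doubling timing applies to tumors with modal ploidy > 3 and mutations
on balanced A2B2 segments: expected VAF `2p/(4p + 2(1−p))` before doubling
(multiplicity 2) vs `p/(4p + 2(1−p))` after (multiplicity 1) — 0.5 and 0.25
in a pure tumor. Each mutation goes to the side with higher binomial
likelihood; the decision boundary equals the likelihood-ratio crossing
(verified against a brute-force grid at depth 77, ≥ 95 % correct labels at
purity 0.6). The doubling event is placed in the earliest clone (root-first
order) whose A2B2 mutations are predominantly (> 50 %) pre-doubling.
Per-clone signature proportions are simple label fractions over each clone's
mutations, flagged low-confidence under 20 mutations.

## Phenotype scores (phenoscores)

TPM is `1e6 (count/len) / Σ(count/len)` per sample. ssGSEA ranks genes
descending, weights in-set ECDF steps by rank^0.75 (average ranks for ties —
a package choice), and sums the running in-minus-out ECDF difference; the
score is deterministic and invariant under monotone transforms. The EMT
composite is mesenchymal minus epithelial enrichment rescaled by the cohort
max-abs into [−1, 1] (positive = mesenchymal lean) — a documented
approximation of the original two-sample KS construction, which the source
only cites. Promoter classes: beta < 0.3 hypomethylated, > 0.7
hypermethylated, else intermediate (strict inequalities). A Wilcoxon
signed-rank paired comparison utility is provided for synthetic demos only;
it is not a reimplementation of count-model differential testing.

## Problem sizes in the tests

The test suite runs the recovery experiments at desk scale: 20 simulations
for purity/ploidy recovery, 15 samples × 5,000 mutations with 50 bootstraps
for the rank-4 signature experiment, 50 replicates for kataegis
sensitivity, 1,000 sites for MSI null calibration, and 2,000 mutations for
the 3-clone design. These sizes were chosen so the full suite completes in a
few minutes while keeping every statistical claim testable at its stated
tolerance.
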