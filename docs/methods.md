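# Methods

This note documents the models behind `ntracts`, the defaults and why,
what the synthetic-data generators do and do not emulate, and the
numerical choices a user auditing results will want to know.

## Recent vs background Neanderthal ancestry

A single Neanderthal ancestor `g` generations back transmits ancestry
as long chromosome tracts. We model the carrier lineage as a fully
Neanderthal gamete recombined against fully modern homologs in each of
`g` successive meioses (Haldane model: crossovers a Poisson process at
1 per 100 cM, uniform start phase, no interference). Under this model
tract lengths away from chromosome ends are ~Exponential(g/100 per cM)
and the expected Neanderthal fraction *of that genome copy* is 2⁻ᵍ. A
parent therefore contributes half of a gamete's ancestry at g = 1, and
the fraction halves per generation. The older, population-wide
admixture pulse (default age T_bg = 2,000 generations ≈ 50 kyr at 25
yr/generation) is modelled as a stationary two-state Markov process
per haplotype with stationary archaic fraction α_bg = 0.02 and mean
archaic tract length 100/T_bg = 0.05 cM; such tracts exceed 5 cM with
probability e⁻¹⁰⁰, so they cannot contaminate the dating sample.

Note an intrinsic approximation shared with the dating model: in an
exact pedigree, the first meiosis out of the Neanderthal creates no
ancestry boundaries. We use the `g`-breaking-meioses form throughout so
that the generator and the estimator describe the same process; the
alternative bookkeeping shifts `g` by one, well inside the confidence
intervals at the sample sizes involved.

## Ancestor dating

For tract lengths ℓᵢ above a threshold t (default 5 cM, chosen to
exclude the background), memorylessness of the exponential gives
excesses ℓᵢ − t that are again ~Exp(g/100), hence

    L(g) = n·log(g/100) − (g/100)·Σ(ℓᵢ − t),   ĝ = 100·n / Σ(ℓᵢ − t).

L is strictly concave; the profile 95% CI takes all g within 1.92
log-units (χ²₁/2) of the maximum on a grid g ∈ [1, 200], step 0.01,
flagging intervals clipped at the grid edge as open. A parametric
bootstrap CI (resample n lengths from Exp(ĝ) + t, percentile interval)
is provided as an alternative; the two agree as n grows.

The likelihood uses lengths only. The tract *count* also carries
information about g, but it depends on detection power and on the
background mixture, so conditioning on the observed count is the
conservative choice. Two biases are knowingly accepted and documented
rather than corrected: chromosome-end censoring shortens observed
tracts (pushing ĝ up), and with few segments E[100n/Σ] exceeds g
(Jensen). At realistic segment counts (2–10) the median end-to-end ĝ
for a g = 6 ancestor sits near 8 with wide CIs; the profile CI's
measured coverage of the true g is 0.92–0.94 at g ∈ {4, 7, 12},
against a 0.95 nominal level. The coverage experiment pools the three
g strata, because a g = 12 ancestor leaves a usable (> 5 cM) segment
in only ~5% of pedigrees and a per-stratum proportion at feasible
replication would be dominated by binomial noise; coverage is defined
over datasets with ≥ 1 usable segment (the estimator's precondition).

## f-statistics

Population frequencies come from allele counts; a pseudo-haploid sample
contributes one chromosome, a diploid two. Per-SNP contributions:
f2 = (pᵢ−pⱼ)², f3(c;a,b) = (p_c−p_a)(p_c−p_b),
f4(a,b;c,d) = (p_a−p_b)(p_c−p_d). The small-sample heterozygosity
correction p(1−p)/(n−1) is applied by default to f2 (both populations)
and f3 (target population) and dropped where n = 1 (undefined); f4 and
D are unbiased without it. D is the ratio of sums
Σ(p_a−p_b)(p_c−p_d) / Σ(p_a+p_b−2p_ap_b)(p_c+p_d−2p_cp_d), not a mean
of ratios; f4 is reported as a mean of per-SNP products. A SNP enters a
statistic only when every population in it is non-missing there.

Standard errors use the weighted block jackknife with fixed 5 Mb
windows anchored at position 0 of each chromosome (the window size is
standard; anchoring at 0 makes blocks deterministic). With block
weights mⱼ (SNP counts), h_j = n/m_j, τⱼ = hⱼθ̂ − (hⱼ−1)θ̂ⱼ and
θ̂_J = gθ̂ − Σ(1−mⱼ/n)θ̂ⱼ, the variance is (1/g)Σ(τⱼ−θ̂_J)²/(hⱼ−1),
which reduces to the plain delete-one jackknife at equal weights. 95%
CIs are ±1.96 SE.

The f4-ratio α = f4(A,O;X,C)/f4(A,O;B,C) is jackknifed as a ratio of
sums over the SNPs shared by both statistics; the result is flagged
unreliable when the denominator's |Z| < 3.

## Admixture graphs

Drift edges carry non-negative lengths in f2 units; admixture edges
carry a proportion and no drift. With w_leaf(e) the probability that a
lineage from a leaf traverses edge e (admixture nodes split flow
α/(1−α)), expected statistics are linear in edge lengths:
E[f2(i,j)] = Σ L_e (w_i−w_j)², and f3/f4 follow from the f2 identities.

Fitting uses the outgroup-f3 basis f3(O;i,j) over all non-outgroup leaf
pairs (including i = j), with a weighted-jackknife covariance matrix
regularised by adding 10⁻⁶·mean(diag) to the diagonal (jackknife
covariances are noisy at small block counts). Edge lengths solve a
non-negative GLS problem (Cholesky-whitened NNLS); each free admixture
proportion is optimised by a deterministic 0.02-step grid with
golden-section refinement (coordinate passes when several are free).
Residual Z scores are reported for every leaf f2 pair, f3 triple and
f4 quadruple against that statistic's own jackknife SE; `worst_abs_z`
is the headline diagnostic, and topology comparison ranks by
(worst |Z|, objective) with ties reported.

Identifiability caveats: only the *sum* of the two root-adjacent edges
is identifiable from f-statistics (the rank check merges those columns
before flagging a design as deficient), and a mixing proportion is only
identifiable when each admixing source lineage has a sampled reference
(in the bundled recovery scenario, leaves Q1/Q2 hang off the two source
branches; without them the free edge lengths absorb any α, which the
noiseless experiments confirm). Inversion of noiseless tree data is
exact once the outgroup edge is pinned.

## Tract-detection HMM

The genome is divided into 0.05 cM bins (configurable; the 0.2 cM
*reporting* cutoff is separate). Hidden states are Neanderthal copy
numbers {0, 1, 2}; each haplotype is an independent two-state chain
with stationary archaic fraction F (default 0.03) and switch intensity
τ per cM (default 0.2, i.e. ~5 cM tracts a priori); the copy-number
transition matrix is the product chain, P(i→j | d) built from
e^(−τd)·I + (1−e^(−τd))·π per haplotype.

Emissions are per-read: with q_k = (k/2)p_nea + (1−k/2)p_afr,

    P(derived | k) = c·p_cont + (1−c)·[(1−e)·q_k + e·(1−q_k)],

summed in log over the reads of a bin; frequencies are pseudo-count
smoothed ((p·n+0.5)/(n+1), n = 100) and probabilities clipped to
[1e−12, 1−1e−12]. Reads are treated as conditionally independent given
the state — within-individual read correlation at a site is ignored, a
deliberate simplification. Decoding is exact forward–backward in log
space; the forward and backward total log-likelihoods agree to < 1e−6
as an internal consistency check. Parameter re-estimation
(`fit_params`) maximises the same likelihood directly over (F, τ[, c])
by bounded Nelder–Mead on transformed scales (tolerance 1e−4, ≤ 100
iterations); a closed-form EM step is not available for the factorised
copy-number chain. Segment calling takes maximal runs of bins with
P(k ≥ 1) ≥ 0.9, merges runs separated by less than one bin, drops
segments under 0.2 cM, and assigns copies = 2 when the k = 2 posterior
mass inside the segment exceeds the k = 1 mass. No per-library
contamination, no run-length decoding and no third (Denisovan) source
are modelled.

## Ancient-DNA QC

*Deamination filter*: a fragment is "putatively deaminated" when a
C→T substitution appears within the first and/or last three aligned
positions (inclusive OR). The damage-masking window for genotype
calling is five positions — the two windows are distinct and both
configurable.

*Conditional deamination contamination estimate*: for each terminal
position k ∈ {1,2,3} at either end, C→T rates at reference-C positions
are observed over all fragments (rate (1−c)·δ_k, because present-day
contaminants carry no deamination) and over fragments already
deaminated at the opposite end (an endogenous-only subset under
end-independence; rate δ_k). c and the nuisance rates are estimated by
joint binomial ML over the disjoint strata, with the opposite-end flag
frequencies constraining (1−c)·β per end; the SE is the profile
curvature in c. The one-position special case is the classical
ĉ = 1 − r_u/r_c. End-independence of deamination is an assumption; it
holds in the generator and approximately in real libraries.

*X-chromosome estimate (males)*: one X means every endogenous read
should match the site consensus up to error. The consensus is
leave-one-out majority with margin ≥ 2 (so a single contaminant read
cannot flip it and depth-1 sites drop out — without this the estimate
is biased). The likelihood
P(read) = c·q_read + (1−c)·[(1−e) if match else e] is maximised over
(c, e) with L-BFGS-B; fewer than 50 informative sites flags the result.

*Sex*: ρ = (X fragments / X target sites) ÷ (autosomal fragments /
autosomal sites), computed on deaminated fragments; the Clopper–Pearson
interval on the X share converts to a CI on ρ; male requires the whole
CI below 0.6, female above 0.8, otherwise unresolved.

*Pairwise mismatch rate*: mismatches over jointly called sites between
two pseudo-haploid call sets. Two samplings of one diploid disagree at
half the heterozygous sites, unrelated genomes at roughly twice that
rate; the default decision midpoint is 0.18 with < 500 overlapping
sites returning "inconclusive". The threshold is a fallback — in a real
cohort it should be set between the observed same-individual and
unrelated distributions.

## Overlap and desert statistics

Ancestry vectors mark 100 kb windows overlapped by any segment; vector
pairs are compared by Pearson correlation with a percentile block
bootstrap over 5 Mb blocks (both sizes configurable; binary vectors
make Pearson equal to the phi coefficient). Groups of correlations are
compared by the two-sided Mann–Whitney/Wilcoxon rank-sum test (exact
null for small tie-free samples, tie-corrected normal otherwise).

The desert test measures Σ bp overlap between segments and desert
regions, then permutes by re-placing each segment uniformly at random
within a callable interval of its own chromosome (placement weighted by
available span; length preserved; placed segments may overlap). This
within-chromosome scheme preserves each chromosome's segment budget.
The one-sided depletion p-value is (1 + #{null ≤ observed})/(1 + n_perm),
so p ∈ [1/(n_perm+1), 1]; overlap with the cumulative-coverage function
G makes each permutation O(1) per segment. Under a random-segment null
the p-values are uniform (KS-checked in the tests).

## Synthetic data: what it does and does not emulate

Graph frequencies: the root draws Uniform(0.05, 0.95); each drift edge
applies Balding–Nichols sampling with the Beta parameter scaled by the
parent's mean heterozygosity so that the *realised* f2 equals the edge
length — this keeps simulated drift in the same units the graph fitter
estimates, at the cost of reinterpreting very long edges (an error is
raised when the implied within-edge F would reach 1). Read simulation
fixes haplotype alleles once (drawn from the ancestry-matched source
frequency), then draws Poisson(λ) depth per SNP, contaminant status
(contaminant reads draw from the contaminant population and are never
deaminated), a uniform haplotype, error flips, fragment lengths
35 + Geometric (mean 50 bp), and terminal C→T flags with probability
δ·ρ^(k−1) at distance k (defaults δ = 0.3, ρ = 0.5) at reference-C
positions (C probability 0.25 per terminal position). Males halve X
coverage and carry one X haplotype.

Not emulated: linkage disequilibrium between panel SNPs beyond the
ancestry tracts themselves, deamination of the SNP allele itself (the
damage masking is therefore exercised by constructed cases, not by the
generator), library-size and duplicate structure, reference bias, and
genuine sequence context. Passing recovery tests therefore show the
estimators are correct *under their stated models*, not that those
models capture every artefact of real libraries.

The archaic-informative panel generator pushes Neanderthal and African
frequencies apart (mean separation 0.85) to mimic ascertainment of
archaic-diagnostic sites, with the contaminant population tracking the
African frequencies.

## Experiment scales

The bundled experiments are desk-scale by design: genomes of 200–3,500
cM with 20–100 SNPs per cM, 50–100 k SNPs for frequency-level
experiments, 20 k fragments for contamination recovery, and 25–100
replicates per recovery experiment. Recovery of the conditional
contamination estimate is assessed on the mean of five 20 k-fragment
simulations per contamination level, because a single draw has
SD ≈ 0.03–0.04 at that fragment count — the replicate mean measures the
estimator's accuracy rather than one draw's luck. Every simulation,
decode and permutation is reproducible bit-exact from (spec, seed).
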