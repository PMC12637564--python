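# Methods

This note documents the models and procedures implemented in `dmsd`, the
parameter defaults and why they were chosen, the numerical decisions, and the
limits of what the synthetic studies can demonstrate.

## Study design

A study consists of a panel of Src-family kinase domains (254 residues,
encoded by a 765-nt ORF including the stop codon) each paired with a set of
tethered peptide substrates. Libraries are barcoded with 16-bp barcodes whose
first two bases are a kinase-identifying tag (AG/CT/TA for Fyn/Lck/c-Src);
domain positions map to full-length numbering via per-kinase offsets
(+269 Fyn, +260 Lck, +244 c-Src). Saturation mutagenesis uses the NNK codon
alphabet (N = any base, K = G/T): 32 codons covering all 20 amino acids plus
the TAG stop, so the variant universe per kinase is every NNK codon differing
from the wild-type codon at each position, plus the wild type.

## Barcode–variant lookup

Long reads are parsed by exact anchor matching (a configurable Hamming
tolerance exists for real data, default 0): vector context, then the barcode,
then the constant cassette anchor (`GCCTAGGCAGCTATGACCATGATTACGCCAAGCG`),
then the ORF, then a 3′ overhang. Reads missing either flanking anchor, with
a tag inconsistent with their library, or with an ORF that is not 765 nt, are
rejected with a per-flag tally — no silent drops.

Reads sharing a barcode form a pileup. Per position the four base hypotheses
are scored with likelihood 0.9 for the observed base matching the hypothesis
and 0.1/3 per mismatch (the two values sum to 1 over the four outcomes; an
exact-0.03 mode is available, in which the unnormalised weights are absorbed
by the posterior normalisation), a uniform 0.25 prior, and log-space
accumulation so high-depth pileups cannot underflow. The consensus takes the
argmax base per position with deterministic lexicographic tie-breaking
(A < C < G < T); `N` observations contribute no likelihood. The joint
posterior of the consensus — the product of per-position maximum posteriors,
exact under position-wise independence — gates entry into the lookup table at
0.99. Conflicting duplicate barcodes keep the higher-confidence call and are
logged. A consequence of the joint gate worth knowing: singleton read groups
over the full ORF have joint posterior 0.9⁷⁶⁵ ≈ 0 and are always rejected, so
the table only ever contains multiply-covered barcodes.

The bulk simulation path (`build_lookup_from_pileup`) evaluates the identical
posterior arithmetic but exploits that error-free positions all share one
pileup (R reads of the template base): their posterior is computed once, and
only positions that drew errors — Binomial(R, e) per position, split
multinomially over the three wrong bases, exactly the distribution induced by
i.i.d. per-read substitutions — get individual 4-hypothesis evaluations. This
makes a 360,000-barcode, 10-reads-per-barcode study callable in well under a
minute without changing any result.

## Fitness scoring

Barcodes are counted by exact identity of the 16 nt 5′ of the cassette anchor
and matched exactly against the lookup table. Filters, in order: unmapped
barcodes; tag/kinase inconsistency; pre-selection coverage — every
pre-selection replicate must exceed 20 reads (strict: a count of exactly 20
is removed); more than two amino-acid changes. Each rule's removals are
logged, and filtering is idempotent.

Per-barcode enrichment is the depth-normalised log₂ fold change
log₂((post+½)/D_post) − log₂((pre+½)/D_pre) per replicate; the 0.5
pseudocount keeps zero counts finite and its distortion is <10⁻³ for counts
above ~700. Outliers are removed within each variant group per replicate at
|z| > 2 (population standard deviation; groups of ≤2 barcodes or zero
variance are exempt, since z is not meaningful there). Variant scores are the
mean over surviving barcodes and replicates with s.e. = s.d./√n; wild-type
and synonymous barcodes pool into per-kinase neutral classes that later
anchor zero.

This replicate-averaged log₂FC estimator deliberately replaces count-level
hierarchical fitness models: downstream stages consume per-variant scores
with standard errors, and the defined estimator preserves that contract while
remaining exactly auditable against the generator's latent truth (on
noise-free expected counts the collapsed scores reproduce the latent rank
order exactly, Spearman ρ = 1).

## Growth-rate extraction

OD₆₀₀ time courses (60 h at 15-min intervals, starting OD 0.005) are smoothed
with a centered 25-point moving average (window truncated symmetrically at
the boundaries). After a 100-smoothed-point burn-in, exponential-phase points
are those whose forward-difference derivative of smoothed OD per hour exceeds
a dynamic threshold τ, started at 5×10⁻³ and divided by 1.25 until at least
25 points qualify (loop capped at 200 iterations); if that fails, or the
final OD is below 0.05, the entire post-burn-in trace is used. The growth
rate is the least-squares slope of smoothed OD against time over the window;
a log-OD mode recovers the exponential rate directly (within 0.3 % on an
analytic exponential). τ has OD-per-hour units; the text the procedure
derives from prints no units, and per-hour makes the default threshold land
in the realistic dynamic range of yeast curves. The linear-OD default follows
the procedure's wording; because scores are subsequently z-scored within each
kinase and affinely mapped onto [0, 2], both modes give identical rankings on
monotone curve families. Rates {1, 2, 3} within one kinase map exactly to
{0, 1, 2}; zero within-kinase variance maps to 1.0 with a warning.

One geometric caveat: with a 25 h burn-in (100 points × 15 min) and starting
OD 0.005, a logistic culture growing faster than ~0.17/h passes its
inflection before the burn-in ends, so the selected window then lies on the
saturating tail. Window-bracketing checks use rates ≤ 0.12/h where the
inflection falls inside the analysed trace; the least-squares slope matches
the mean analytic dOD/dt (within 2 %) when the window is roughly symmetric
about the inflection.

## Hierarchical decomposition

The observation model is

    abundance[i,j,k,l] ~ Normal(α[i,k,l], σₐ)
    phospho[i,j,k,l]   ~ Normal(α[i,k,l] + c[i,k,l] + s[i,j,k,l], σₚ)

Folding stability is independent of which short peptide the kinase is
tethered to, so the per-substrate abundance measurements act as technical
replicates of one α; activity c is likewise substrate-shared; specificity s
varies with all four indices. s is identifiable against c only up to a
per-(i,k,l) shift across substrates, so a soft sum-to-zero constraint
(pseudo-observation 0 ~ Normal(Σⱼ s, 0.05²)) pins that direction; the
reported s is therefore the substrate-centered projection of any raw truth.

Priors: α and c are hierarchical zero-centered Normals with Half-Normal(1)
scales. s has prior Normal(0, 0.2²) with the scale **fixed** by default
(`tau_s_mode="fixed"`), optionally hierarchical (Half-Normal(0.2)) or
heavy-tailed (Student-t via `s_df`). The fixed default is a deliberate
design decision: with a single phospho observation per (i,j,k,l) cell, a
learned specificity scale and a free observation noise are mutually
confounded — whichever is free absorbs the sparse specificity signal (a
learned τ_s collapses toward zero while σₚ inflates; conversely a free σₚ
under a fixed broad τ_s collapses to zero and everything is "specific").
The fixed 0.2 scale encodes the empirical fact the model is built around —
specificity effects are roughly an order of magnitude smaller than abundance
and activity effects — and acts as the regulariser that keeps the background
at zero while letting real effects through.

For the same identifiability reason, the observation noise uses **known
per-cell measurement standard errors** when the score tensor carries them
(the fitness module reports per-variant s.e.; the synthetic generator
attaches its noise s.d.), in the standard meta-analytic fashion; free global
σₚ, σₐ with Half-Normal(0.5) priors remain the fallback when no s.e. is
available. Missing cells contribute no likelihood.

Sampling is by an exact blocked Gibbs sampler: the per-cell effect block
(α, c, s₁…s_J) is jointly Gaussian given the scales and is drawn as one
batched (J+2)-dimensional Normal via Cholesky factorisation — eliminating
the α–c anticorrelation and the sum-to-zero coupling from the chain's
autocorrelation — while scale parameters use univariate slice sampling plus
interweaved (ancillarity–sufficiency) non-centered updates, whose conditional
is a truncated Normal, to avoid the classic scale-funnel collapse on
near-null data. Four chains of 500 draws after 500 warm-up sweeps converge on
the reference recovery simulation (2 kinases × 3 substrates × 40 positions ×
19 mutations, α,c ~ N(0, 0.5²), 5 % sparse s = ±0.3, σ = 0.1) with max split
R̂ ≤ 1.01; fits exceeding R̂ 1.01 are flagged unconverged. All randomness
flows from a single integer seed.

Summaries report posterior means, equal-tailed 94 % credible intervals,
directional probability max(P(θ>0), P(θ<0)) and the local false-sign rate
(1 − directional probability). A specificity effect is called significant
only if its directional probability is ≥ 0.97 (equivalently, the 94 % CI
excludes zero — the one-sided convention) **and** a two-sample KS test
against matched seeded prior draws rejects at α = 0.05, guarding against
narrow posteriors that have not actually moved. On the reference simulation
this dual gate flags about half of the truly specificity-determining cells
with 100 % sign agreement (against the substrate-centered truth) and a ~2 %
flag rate on fully null data — within twice the ~5 % nominal rate the
(0.97, 0.05) thresholds imply.

## Harmonisation, classification, enrichment

Abundance: per kinase, scores are zero-centered on the synonymous mean, then
scaled by (reference / centered nonsense mean) so stop-gain baselines
coincide; the reference is the cross-kinase mean of centered nonsense means.
Centering precedes scaling — the reverse order cannot land the nonsense means
exactly on the reference (both orders are available via config). Variant
scores are then averaged across substrate backgrounds. The operation is
idempotent. Activity: positives are divided by the per-kinase mean positive
score, negatives by |mean negative|, zeros untouched; a per-kinase additive
offset then aligns the mean of high-confidence positives (pre-offset score
> 0.20) to the cross-kinase mean of those means.

Classification is strict at every boundary: activity GoF > 0.24,
LoF < −0.21 (a score of exactly −0.21 is neutral); abundance GoF above the
per-kinase mean positive score, LoF below 0.45 × the mean negative score.
Positional enrichment uses a one-sided (over-representation, upper-tail
hypergeometric) Fisher test of each position against all others, per kinase
and direction, with Benjamini–Hochberg correction across positions and
enrichment at q ≤ 0.10. A position is conserved when enriched in ≥ 2 of 3
kinases; the remaining kinase is rescued if ≥ 2 of its variants there fall in
the bottom (LoF) or top (GoF) 20th percentile of its full score distribution
(nearest-rank percentiles for determinism).

SASA strata follow fixed bins: > 150 Å² strongly exposed (−1), 50–150 Å²
moderately exposed (0), 10–50 Å² buried (1), 2.5–10 Å² strongly buried (2),
< 2.5 Å² core/hydrophobic (3). The printed bin edges leave exactly 50 Å²
uncovered; it is assigned to the moderately-exposed bin, keeping the label
function monotone in SASA.

## Residue graphs and pathways

Contact tables are reduced to replicate means per condition; an edge survives
if either condition's mean frequency exceeds 0.01. Classification tests
conserved first (both means > 0.8 and |difference| < 0.1), then up/down by a
variant-specific mean-difference threshold (0.115 for subtle distributed
rewiring, 0.3 for large local perturbations); sequence-adjacent pairs
touching a classified node re-enter as neighbor relay edges if the contact
existed. Components smaller than 4 nodes are pruned.

Critical residues are the union of: the mutation site, substrate residues
with differential kinase contacts, kinase residues directly contacting the
substrate, and residues of significant structural fragments (each extended
one residue downstream). Minimal pathways connecting them solve the Steiner
tree problem by the classical 2-approximation — metric closure over the
terminals (Dijkstra, edge cost 1 − mean contact frequency so strong contacts
are cheap; unit costs optional), minimum spanning tree of the terminal
closure with ties broken by sorted node pairs, shortest-path expansion, MST
of the expanded subgraph, and repeated pruning of non-terminal leaves. On
trees the result is exactly optimal; on random graphs it is within the
factor-2 guarantee of an exhaustive-enumeration optimum (measured worst
ratio ≈ 1.2 over seeded 12-node suites). Runs of degree-2 non-terminal nodes
whose incident edges are all conserved collapse into supernodes in the
report.

Metastate comparisons binarise contact frequencies at 0.3 (boundary counted
as present) and report per-state sets, the all-state intersection, and
per-state unique contacts. Differential structural fragments use log₂ fold
changes of pseudocounted replicate-mean frequencies, a Welch t-test on logit
frequencies per fragment pair (the upstream tool's test is unspecified; Welch
on the variance-stabilised scale is the defensible default), BH correction
across fragments, and calls gated at FDR < 10⁻⁴ **and** |log₂FC| > 4.

## Synthetic studies: what they emulate, and what they do not

The generator reproduces the study conditions end to end: NNK libraries over
254-residue domains, 16-bp tagged barcodes (collisions redrawn up to 100
times, then a diagnostic failure), long reads with i.i.d. per-base
substitutions and optional anchor dropout, selection counts via deterministic
2^(g·score) amplification (g = 5 generations) followed by multinomial
sampling at the requested depth, logistic growth curves (241 points, OD₀
0.005), and contact tables with planted differential pathways. Latent effects
default to α, c ~ N(0, 0.5²) and s = ±0.3 with 5 % density — specificity an
order of magnitude below the other effects; synonymous and wild-type cells
are pinned to zero (the neutral anchor) and stop-gains carry an additional
−1.5 abundance shift so nonsense variants anchor the nonfunctional baseline,
a realistically strong destabilisation that makes nonsense-mean rescaling
well-posed. Barcodes per variant default to 15, the middle of realistic
10–25× coverage. `sample=False` returns expected (real-valued) counts — the
infinite-depth limit used for exact-rank checks.

Not emulated: PacBio quality strings (constant Q40) and indel errors
(substitutions only); PCR amplification bias and barcode-frequency skew;
replicate batch effects beyond i.i.d. condition noise; real kinase sequences
(wild types are random sense-codon draws, so position-specific structural
context is absent); and any nonlinearity between latent score and growth.
Passing tests therefore demonstrate that each algorithm recovers the truth
its declared model generates — consensus exactness, filter semantics,
estimator fidelity, sampler correctness, graph guarantees — not that the
declared models capture every failure mode of real sequencing data.

## Numerical and engineering notes

- All posterior arithmetic in log space; slice sampling operates on log
  scales with stepping-out capped at 30 doublings.
- Argmax ties everywhere break deterministically (lexicographic bases,
  sorted node ids).
- Every stochastic artifact is reproducible from a single integer seed;
  independent streams are spawned via `SeedSequence`.
- The bulk pileup path is distributionally exact (Binomial/Multinomial
  sufficient statistics) and shares the posterior code with the per-group
  path.
- Fisher p-values use the survival function of the hypergeometric
  distribution; tests audit them against exact integer-arithmetic tail sums
  to 10⁻¹⁰.

## Known limitations

- The decomposition assumes linearity of the phospho score in its three
  components and Gaussian noise; saturating growth-to-score links and
  epistasis are out of scope (single-variant studies only).
- With one observation per specificity cell, detection power at |s| = 0.3 and
  σ = 0.1 is intrinsically limited (~50 % recall at the dual threshold);
  the gate is tuned for sign reliability, not recall.
- The growth module estimates a single exponential-phase slope; lag time and
  carrying capacity are not modelled.
- Anchor matching is exact by default; highly error-prone long reads will
  lose yield unless the Hamming tolerance is raised.
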