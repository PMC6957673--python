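# Methods

`mitodate` implements the analysis chain of a mitogenome divergence study:
uncorrected distances and indel summaries between aligned mitochondrial
genomes, amino-acid replacement mapping onto the branches of a three-taxon
tree, GTR+Γ+I maximum-likelihood phylogenetics with nonparametric bootstrap
confidence intervals for branch lengths, and divergence dating by penalized
likelihood (correlated rates) and by relaxed-lognormal-clock MCMC with
fossil calibrations. This note records the models, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## Distances and indels

All pairwise comparisons use *pairwise deletion*: a column contributes only
when both residues are unambiguous bases (A, C, G, T). Gaps, N and IUPAC
ambiguity codes are treated as missing; they never count as differences and
never enter the denominator. A pair with no comparable column raises an
error rather than returning 0, since a silent zero would fabricate
identity. Per-gene distances go through gap-aware coordinate mapping: gene
coordinates are 1-based inclusive on the ungapped reference sequence
(GenBank convention), and columns where the reference is gapped inside a
gene span are retained as insertions relative to the reference.
Minus-strand features are reverse-complemented (IUPAC-aware) so extracted
genes read in coding orientation. Indel events are maximal gap runs carried
by exactly one sequence of a pair.

## Protein-level comparison

CDS features are translated under NCBI genetic code table 2 (vertebrate
mitochondrial: AGA/AGG stop, ATA Met, TGA Trp); any codon containing a gap
or ambiguity becomes `X`, and `X` never makes a column variable or counts
as a difference, so missing sequence at the edges of a partial genome
cannot inflate replacement counts. With exactly three taxa, each variable
column is assigned by parsimony: a state unique to one tip maps to that
tip's terminal branch, agreement of the two ingroup tips against the
outgroup maps to the internal branch, and three distinct states are
reported as ambiguous rather than resolved arbitrarily.

## GTR+Γ+I likelihood

The engine is Felsenstein's pruning algorithm over compressed site
patterns with per-pattern log scaling (rescaling every fourth level of the
tree). The rate matrix is scaled to one expected substitution per site at
stationarity; discrete-gamma category rates are the means of the
equal-probability slices of a Gamma(α, α) density; and with invariant
sites the variable categories are rescaled by 1/(1 − p_inv) so branch
lengths remain expected substitutions per site averaged over all sites
(the PhyML/phangorn convention — without this rescaling, branch lengths
would shrink or stretch with the fitted p_inv). Four gamma categories are
used by default. Gaps and ambiguity codes enter as all-ones partial
vectors. The invariant-site term is the stationary probability of the
states compatible with constancy of the pattern; it is constant in the
branch lengths and cached.

Branch lengths are optimized one edge at a time by bounded Brent searches
on edge-local likelihood factors (the conditional vectors below and above
the edge), which makes one length evaluation O(patterns) instead of a full
tree pass; lengths are bounded below at 1e-8 to keep the optimizer in the
interior. Model parameters (five free exchangeabilities, three free
frequency log-ratios, α, p_inv) are optimized by L-BFGS-B together with a
global tree-length scale factor; the scale absorbs the strong coupling
between rate-heterogeneity parameters and total inferred change that
otherwise makes the alternation converge slowly. p_inv is bounded to
[0, 0.99] and estimated jointly with α despite the well-known confounding.
The default topology search is none (fixed topology from a
neighbor-joining start on Jukes-Cantor-corrected distances, via dendropy's
NJ with negative lengths clamped to zero); nearest-neighbor-interchange
hill climbing is available and accepts the best improving move per sweep
until none improves.

## Bootstrap and the rate-equality test

Nonparametric bootstrap resamples alignment columns with replacement
(multinomial over compressed patterns), holds the topology fixed at the ML
tree, and re-optimizes branch lengths per pseudoreplicate starting from
the ML values (re-optimizing the model per replicate is available but off
by default, for speed). Per-branch 95% intervals are 2.5/97.5 percentiles,
with branches named by the tip bipartition they induce. The rate-equality
test for two branches uses the bootstrap distribution of the length
difference: the two-sided tail fraction 2·min(P(d ≤ 0), P(d ≥ 0)) is the
p-value, and the per-branch intervals are reported alongside for the
CI-overlap presentation.

## Penalized-likelihood dating (correlated rates)

Given a rooted tree with ML branch lengths, node ages (Ma, tips at 0) and
per-branch rates maximize

    Σ_j [x_j log(r_j t_j) − r_j t_j]
    − λ [ Σ_{non-root} (r_j − r_parent(j))² + Var(rates of root children) ]
    − soft calibration penalty,

where x_j is the branch's expected substitution count (ML length ×
alignment length, continuous — no rounding, which avoids degeneracy for
near-zero branches; the constant log x! term is dropped) and t_j the
duration implied by the ages. Rate changes between adjacent branches are
penalized quadratically (the correlated-rate model); λ defaults to 1 and
is surfaced in the CLI and recorded in outputs (cross-validation for λ is
out of scope). Calibrations are age windows on MRCAs applied as quadratic
penalties outside [min, max] with weight 10 × alignment length (100× that
for hard calibrations); the penalty is exactly zero whenever all
calibrated ages are inside their windows.

Numerics. The profile likelihood over ages is exactly flat (for any
durations, rates can reproduce the ML lengths), so a naive joint
parameterization makes the optimizer chase a penalty signal ~10 orders of
magnitude below the objective. Ages are therefore parameterized as
proportions of the parent age (root age in log space), and rates as the
profile-optimal value x_j/t_j times exp(δ_j): the likelihood then depends
only on δ and age moves act purely through the penalties, which removes
the cancellation. Because a time-reversible likelihood cannot place the
root along the rooting edge, the two root-child branches' counts are
treated as one merged observation by default (`merge_root_edges`); the
exposed objective function keeps the plain per-branch form. Optimization
is L-BFGS-B from several starts — a data-driven start with ages
proportional to node heights under a crude clock, plus seeded
perturbations of it — each iterated with fresh restarts until stalling,
keeping the best.

## MCMC dating (relaxed lognormal clock)

On a fixed rooted topology, branch length = duration × clock mean ×
branch multiplier. Priors: iid lognormal multipliers with mean 1 (location
−σ²/2), σ ~ Exponential(3) (a tight prior on the relaxed-clock spread, in
line with common practice); a pure-birth (Yule) prior on internal node
ages with birth rate given an Exponential(10) hyperprior (mean 0.1/Ma);
normal calibration priors whose 2.5%/97.5% quantiles equal the fossil
windows (mean = midpoint, sd = width/3.92); a bounded log-uniform prior on
the clock mean. The substitution model's exchangeabilities and base
frequencies are held fixed (typically at their ML estimates); α and p_inv
are sampled with bounded log-uniform/uniform priors. Fixing the topology
and the exchangeabilities keeps a desk-scale single chain effective; both
reductions are deliberate and documented here.

Proposals: a uniform slide of one internal node age within the interval
allowed by its parent and children (symmetric), a multiplicative scale of
a whole subtree's internal ages (Jacobian k·u for k scaled nodes — this
operator is what makes shallow, strongly correlated clades mix), a scale
of the root height above its older child, and multiplicative scales of one
multiplier, the clock mean, σ, the Yule rate and α, plus a reflected slide
of p_inv. Moves that do not touch the likelihood (σ, Yule rate) reuse the
cached likelihood. Chains are reproducible bit-for-bit given the seed.
Defaults are desk scale (2×10⁵ generations, sampling every 100, 10%
burn-in); the study-scale settings (10⁷/10³/10⁶) are available through the
same config.

Summaries: the HPD interval is the shortest sorted window containing the
requested mass; the effective sample size uses the
initial-positive-sequence truncation of the autocorrelation sum, with a
constant trace reported as n with a degeneracy warning.

## Synthetic data

Sequences are simulated site-wise from the exact transition matrices
(end-point sampling; event-level simulation is unnecessary because only
tip states are consumed). Site rates are drawn once per site — a gamma
category, zeroed with probability p_inv, times an optional per-column
scale profile — and shared across all branches. Deletions are planted as
gap runs in a named bearer (a stochastic indel process is out of scope),
and unsequenced regions are masked with N.

`latimeria_scenario` emulates the study system: 27 mitogenome-length
sequences — a 25-genome low-diversity clade (coalescent topology, depth
calibrated so the deepest pair expects 10 differing sites genome-wide), a
two-genome lineage pair whose depth is calibrated so the expected number
of differing sites over the ~8.2 kb sequenced half-genome is 149 and whose
COI rate scale is calibrated so the expected barcode (first 655 COI sites)
distance is 0.0122 — plus a 17-feature annotated layout (11 tRNA, 2 rRNA,
3 CDS and the control region) with per-gene rate scaling (fast D-loop,
slow tRNAs), five planted deletions in the new-specimen analogue and two
in the reference, and an N mask over its unsequenced half. The generating
model is a mitogenome-like GTR+Γ+I (A-rich/G-poor, strong transition bias,
α = 0.3, p_inv = 0.35).

`dated_vertebrate_scenario` is a 10-taxon dated tree spanning the three
fossil calibration windows (root 419 Ma; amniote–amphibian 340 Ma;
reptile–mammal 320 Ma), with a 13 Ma shallow split in a 4-genome
coelacanth-like clade and 5-fold among-lineage rate variation. The rate
outliers are placed away from the focal shallow clade — a fast
primate-like mammal lineage (the source of the classic NJ artifact) and a
slow lungfish lineage — while the coelacanth lineage runs near the
tree-average rate. This placement mirrors the study system and matters:
a correlated-rate (smoothing) dating model cannot localize an abrupt
rate jump on the long unbroken stem of the focal clade, and simulations
that put the jump there defeat penalized-likelihood dating regardless of
implementation (ape's `chronos` behaves the same way on such data). The
clock mean is 1.2e-3 substitutions/site/Ma.

What passing tests show — and do not. The generator shares the likelihood
engine's model family, so recovery tests validate the estimators under a
correctly specified model with independent sites; they do not probe
alignment error, codon structure, selection, or saturation beyond what
GTR+Γ+I represents. Indels are planted, not evolved. Problem sizes in the
test suite are chosen for desk-scale runs: dating recovery uses 4000-site
alignments over 20 seeds (penalized likelihood, 25% median-error
check) and 1500-site alignments with 2×10⁴-generation chains over 20
seeds (MCMC HPD coverage, on clocklike data where calibration of the
sampler is well defined); bootstrap coverage uses 60 three-taxon runs of
100 replicates. The acceptance script averages simple counts over three
replicate simulations and takes dating point estimates as medians over
five replicate datasets, because single realizations of a ~150-count or a
two-short-branch age are dominated by Poisson noise.

## Known limitations

- Branch-length bootstrap and dating assume the fixed (ML) topology is
  correct; topology uncertainty is only partially explored via NNI.
- The penalized-likelihood age estimate inherits the correlated-rate
  model's bias wherever true rates jump abruptly along a single long
  branch; λ is not cross-validated.
- The MCMC sampler is a single chain without coupling; convergence should
  be judged from the reported ESS and acceptance rates.
- Site-model parameters (α, p_inv) are weakly identified on short
  alignments; the dating chain therefore holds the exchangeabilities and
  frequencies at their ML values and should be given the ML α/p_inv as
  starting values.
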