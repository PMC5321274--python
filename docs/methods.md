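# Methods

This note records the models, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Homolog pairing

Paralogs are within-species best matches, orthologs between-species best
matches, computed from 12-column tabular similarity hits. "Best" is ranked
by bitscore, ties broken by longer alignment and then lexicographic partner
id; the ranking metric is a package choice, since only "best matches" is
specified by the underlying protocol. By default a pair is emitted only
when the two genes are each other's best match (reciprocal best hit, the
standard orthology heuristic); `require_reciprocal=False` admits
one-directional best matches. Self hits are always discarded. Isoforms
sharing a parent gene — recognised by a configurable id pattern, default a
Trinity-style `_i<N>` suffix — are excluded before ranking so assembly
redundancy cannot masquerade as paralogy. When several hits connect the
same two genes, the longest alignment is kept. Retained pairs must reach
150 bp of alignment at ≥ 60% identity (closed boundaries), guaranteeing at
least 50 codons for rate estimation.

For desk-scale work without BLAST, `all_vs_all_local_align` runs a local
aligner (match +1, mismatch −2, gap open −2.5, extend −0.5) and converts
raw scores to approximate bitscores/e-values with fixed Karlin–Altschul
constants (λ = 1.33, K = 0.621). These e-values are calibration-grade, not
BLAST-grade; they exist so the e-value threshold is exercised end to end.

## Coding regions, codon alignment, and Ka/Ks

Coding regions come from a six-frame longest-ORF scan: the longest
stop-free stretch (≥ 150 nt) wins, ties preferring the forward strand and
lower frame offset. The ORF need not begin with ATG (`require_atg` turns
that on): transcript fragments frequently truncate the 5' end.

Pairs are aligned at the protein level (global, BLOSUM62, gap open 10 /
extend 0.5 — conventional defaults) and back-translated. Gap-containing
codon columns are removed (`gap-policy drop-columns`); dropping whole
gapped pairs is available since the underlying protocol is ambiguous on
this point. Columns containing stop codons are also removed. Alignments
retaining fewer than 50 codons are dropped and counted.

Rates use the Nei–Gojobori (1986) counting method with the standard
nuclear code: per-position synonymous site fractions (changes to stop
codons count as nonsynonymous, so S + N = 3 · codons exactly), observed
differences averaged over all minimal mutational pathways between codons
(pathways through stops excluded; if every pathway is blocked, all are
used), and Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p). A proportion
p ≥ 3/4 flags the estimate as saturated; such pairs are excluded from
dating. ω = Ka/Ks is undefined when Ks = 0. NG86 was chosen over
ML codon models (codeml/yn00 with F3by4) because it is exactly specifiable
and testable against a brute-force pathway-enumeration oracle; the clock
and mixture results consumed downstream depend on Ks peaks, not on the
estimator brand, and a yn00-style estimator could be added behind the same
interface.

The codon-pair simulator places Poisson-distributed synonymous and
nonsynonymous single-nucleotide events on a uniform sense-codon ancestor,
never creating stops. Two-fold degenerate sites revert more often than the
Jukes–Cantor model assumes, so the estimator is expected to be a few
percent low at high divergence; at Ks = 0.4 with 500 codons the measured
mean error is ≈ 0.002, far inside the ±0.05 recovery band.

## Clock calibration

KDE peaks use a Gaussian kernel with the nrd0 bandwidth rule
(0.9 · min(sd, IQR/1.349) · n^(−1/5)), evaluated on a 512-point grid over
[min − 3h, max + 3h]; the peak is reported at grid resolution without
parabolic refinement (grid spacing is finer than the reported precision).
The clock averages the two outgroup-based rates, C_Ks = (Ks_A/2T_A +
Ks_D/2T_D)/2, with T_A = 80.21 and T_D = 95.75 myr entering as configured
constants — the package never re-estimates node ages. This calibration
attributes the full ortholog Ks to twice the focal species' rate, i.e. it
assumes rate symmetry with the outgroup lineage; no lineage-rate correction
is applied. Pairs with Ks above 2 · C_Ks · 200 are excluded from the
200-myr dating window. Clocks are reported to 3 significant figures,
ceilings to 2 decimals.

## Mixture modelling of Ks / age distributions

Univariate Gaussian mixtures are fitted by EM with 100 random starts
(Dirichlet weights, quantile-sampled means, data-sd spreads) and 100
k-means starts (k-means++ seeding plus Lloyd iterations, computed with
prefix sums on the sorted 1-D data). Convergence is |ΔlogL| ≤ 1e-8 ·
max(1, |logL|), at most 1000 iterations; variances are floored at 1e-6
(Ks²) or 1e-2 (myr²) to prevent singular components; monotonicity of the
EM log-likelihood is asserted on every iteration.

Running all 200 starts to full convergence is wasteful: almost all starts
descend into the same handful of basins. The default schedule therefore
runs every start for 15 burn-in iterations in float32 and polishes only the
8 best in float64 to full tolerance — the short-run/long-run multi-start
strategy of Biernacki, Celeux & Govaert (2003). `short_iters=None`
restores the one-stage behaviour; on the suite's problems the two agree to
within 1e-4 logL.

Model selection minimises BIC = −2 logL + (3k − 1) ln n over k = 2..5;
components are retained only above a strict 20% mixing weight. Ks-scale
components convert to ages by dividing mean and sd by 2 C_Ks. The
SSD-candidate (≤ 25 myr) and WGD-candidate (40–120 myr) labels are a
reporting convenience over age windows, not an inference: Gaussian
components fitted into the rising flank of the L-shaped SSD background do
not represent duplication events, and the steep part of an L-shape is not
well approximated by any small Gaussian mixture. Pooled analyses fit the
combined per-species ages directly on the myr scale.

The gene-tree date fit (`collect_and_fit_dates`) admits k = 1, because a
clean duplication screen is expected to produce a single age peak and
forcing k ≥ 2 would split it.

## Gene-count WGD placement

Copy numbers evolve by a linear birth–death process with one global (λ, μ)
pair — a background duplication/loss process — along the dated species
tree. Transition probabilities use the closed form built from the
single-lineage law (extinction α, geometric β, computed with `expm1` so
λ ≈ μ is exact; λ = μ handled by its limit), with i-fold convolution for i
initial copies; the state space is truncated at 20 copies and a family
whose observed count exceeds the bound is an error. A WGD at the midpoint
of its branch maps i → i + Binomial(i, q). The root carries a single copy
by default (geometric prior optional).

Families enter the analysis only if present in ≥ 2 ingroup species and
≥ 1 outgroup, so the likelihood is by default conditioned on exactly that
observability event. The conditioning probability is computed by the same
pruning over joint states (copy number, ingroup-presence counter capped at
2, outgroup-presence counter capped at 1) — exact under the same
truncation. Unconditioned likelihoods are available (`condition="none"`).

For each hypothesis, (log λ, log μ) are maximised by L-BFGS-B while each
event's q is profiled over the grid 0, 0.1, …, 1.0, alternating until the
grid choices stabilise (at most 5 sweeps). AIC counts 2 + (#events)
parameters; Akaike weights are normalised over the compared hypotheses.
Count patterns are deduplicated with multiplicities before pruning, which
is what makes 3000-family scans cheap.

## Gene-tree screen

A tree passes when it contains a node with exactly two ingroup-only
daughter clades, each holding ≥ 1 member of the deepest-split group (the
blue/white-fruited dogwoods, configurable) and ≥ 1 of its ingroup
complement, with the outgroup elsewhere in the tree. When several nodes
qualify, the oldest is reported — a genome duplication predates
within-clade duplications — and flagged. Ages below the 68-myr fossil
minimum are flagged, never corrected. A far outgroup whose tip-to-root
path exceeds 2× the median path of the other taxa (strict inequality) is
pruned before screening, a deterministic stand-in for a manual curation
step.

## Synthetic data: what it does and does not show

The generator reproduces the statistical structure the analyses assume:
truncated-normal WGD components at 2 C_Ks · age over a single-exponential
SSD background (the background's true shape is only known to be L-shaped;
one exponential is the simplest shape-matching choice), ortholog Ks
scatter of configurable σ (default 0.05 — no empirical noise model exists
for it), birth–death gene counts with a binomial retention event, and gene
trees assembled from the species-tree topology with uniform per-species
dropout. Default clocks are the eight published per-species values;
default planted components sit at 74/22/7 myr.

Planted gene-tree duplication ages are drawn from the target normal
(default N(76.1, 2.7)) truncated only at the 68-myr fossil floor; because
dated gene trees carry their own age estimates, copy subtrees are
compressed to sit just below a drawn duplication age and the outgroup
attachment floats above it rather than being pinned to the species-tree
node.

Passing recovery tests on these cohorts shows the estimators are correct
and well-calibrated **under the generating model**. They do not exercise
assembly artefacts, isoform mis-collapse, alignment error, codon-usage
bias, lineage rate shifts, or gene-tree estimation error beyond uniform
dropout — all real-data failure modes that this package's filters can only
partially absorb.

## Problem sizes

The test suite and the acceptance script scale the experiments to: pooled
mixture recovery over 20 seeds with 4 species × 2000 paralog pairs;
placement recovery over 20 seeds with 3000 families; gene-tree recovery at
98 trees; estimator recovery over 50 replicates of 500 codons; 1e5
Monte-Carlo replicates for the birth–death law. These sizes make every
recovery property measurable with comfortable margins while keeping a full
run on one CPU around ten minutes.

## Known limitations

* NG86/JC saturates near Ks ≈ 2–3; deep components are unreliable and the
  200-myr window already excludes most of that regime.
* One global (λ, μ) pair; no branch-specific rates, no multiple WGDs per
  branch.
* The clock assumes rate symmetry between the focal and outgroup lineages.
* Mixture components in the SSD flank are fitted but not interpretable as
  events; retention filtering is by mixing weight only.
* The internal local aligner's e-values are approximate; use real BLAST
  tabular output for production-scale pairing.
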