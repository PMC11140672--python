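# Methods

This note documents the models, numerical choices and limitations behind
`isoreact`.

## Isotope frame and masses

All masses are monoisotopic under an *active isotope table*. The bundled
table carries C, H, O, N, F, Cl and S with standard isotope masses and
natural abundances, stored as package data (`data/isotopes.csv`) so that
other labeling schemes (e.g. ¹³C) are a configuration change, not a code
change. `relabel_isotope` reorders one element's isotopes so the enriched
isotope becomes principal with abundance equal to the enrichment and the
residual abundance distributed proportionally over the others; relabeling is
idempotent at a fixed enrichment and always renormalizes to 1. The default
labeled frame is ¹⁵N at 0.982, after which "N" everywhere denotes ¹⁵N and
¹⁴N exists only as a minor isotopologue at relative abundance
0.018/0.982 ≈ 1.83% per nitrogen.

Deprotonated ions are modeled as m/z = M − 1.00727646 Da at charge 1
(M − H + e⁻); multiply charged species are out of scope and remain
unassigned. DBE = 1 + C − (H+F+Cl)/2 + N/2 treats halogens as hydrogens and
N as trivalent; O and S contribute nothing. The aromaticity index follows
the Koch–Dittmar convention, AI = (1 + C − O − S − ½(H+F+Cl)) / (C − O − S − N),
clamped to 0 for non-positive numerators or denominators; the standard
(non-modified) variant is used throughout and deliberately not switched
per-call. Sulfur is excluded from the default *element limits*, so it never
enters disinfection-byproduct candidate enumeration, but it is present in
the isotope data because the amino-acid validation fixture contains cysteine
and methionine.

## Candidate enumeration

For a peak at m/z, the neutral-mass window is
[mz/(1+t) + m_p, mz/(1−t) + m_p] with t = tol·10⁻⁶ (default 1 ppm).
Enumeration is a branch-and-bound recursion over elements in descending
mass with interval pruning on the residual mass (a branch dies when the
partial mass exceeds the window or cannot reach it even at maximal remaining
counts); the lightest element is resolved arithmetically. The search is
provably exhaustive over the limit box and is cross-checked in the test
suite against an independent vectorized full-grid oracle (16.5 M count
tuples for C₂₉H₇₂O₁₈N₁₀F₃Cl₈) on 1,000 random m/z values.

Beyond the element limits, candidates must have integer, non-negative DBE
(even-electron neutral molecules). No H/C or heteroatom-ratio heuristics
are applied.

## Confidence scoring

Mass score = exp(−ppm²/2σ²) with σ = tol/2 (0.5 ppm at the default
tolerance). For each candidate, single-substitution isotopologues are
predicted per element as (mass shift, relative intensity n·a_minor/a_principal)
using each element's most abundant non-principal isotope; isotopes with a
per-atom abundance ratio below 10⁻³ (deuterium) are omitted, which reproduces
the conventional ¹³C/¹⁴N/¹⁸O/³⁷Cl (+³⁴S) verification set. An expected
isotopologue is *detectable* when its predicted relative intensity exceeds
0.2/s2n of the monoisotopic peak (i.e. 20% of the peak's implied noise
floor). Each detectable expectation is matched to the nearest free peak
within the ppm tolerance of its predicted position; the deviation is
|obs − exp|/max(obs, exp) on relative intensities, a missing detectable peak
counts as deviation 1, and the isotope score is 1 − mean deviation. Missing
peaks are penalized (not merely unrewarded): on enriched data the
isotopologue pattern is the main disambiguator between near-isobaric
candidates, and a candidate whose predicted ³⁷Cl satellite is absent should
lose to one whose pattern is present.

Confidence = (w_m·mass + w_i·iso)/(w_m+w_i) with default weights ½/½; when
no isotopologue is detectable the confidence falls back to the mass score
alone. Ties break on smaller |ppm|, then on the Hill formula string, so
assignment is fully deterministic. This score is a reconstruction of the
"mass error + isotopic-pattern similarity" idea implemented by assignment
engines in this field; the exact functional form of any particular engine
is not public, so the weights and σ are exposed in `AssignmentConfig`.

Peaks are assigned in ascending m/z. Because ¹³C/¹⁸O/³⁷Cl satellites lie
*above* their monoisotopic peak, they are claimed as isotopologues before
being visited and never become spurious compounds; the ¹⁴N satellite lies
below its parent, is generally unassignable as a formula of its own (no
element combination in the default space mimics a −0.99703 Da shift within
1 ppm), and is claimed retroactively when the parent is assigned. A peak is
either one assignment's monoisotopic peak or one assignment's isotopologue,
never both.

## Filtering, controls, consensus

Peak filters are strict inequalities (s2n > 4, intensity > 10⁶), matching
the acquisition's picking thresholds; boundary peaks are dropped. Peaks
closer than 0.1 ppm merge on peak-list construction (intensity-weighted
m/z, summed intensity) — the merge tolerance is an implementation choice,
exposed on `PeakList`. Control exclusion removes any formula assigned in
any control replicate and reports it as a contaminant. Replicate consensus
keeps formulas present in **all** replicates (relaxable via
`min_replicates` for sensitivity analysis), averages their monoisotopic
intensities arithmetically, and reports |intersection|/|union| as a
reproducibility diagnostic.

## Diversity and summaries

Shannon H = −Σ pᵢ ln pᵢ in nats by default; the log base is exposed because
published index values depend on it, and H is invariant to intensity
rescaling either way. Zero-intensity entries are excluded rather than
treated as limits. Composition summaries (mean m/z, DBE, AI, H/C, O/C,
element counts) are unweighted by default, with intensity weighting opt-in;
the two coincide for equal intensities. Spearman's ρ uses average ranks for
ties and raises on constant input. Significance testing (ANOVA, t-tests,
correlation p-values) is left to standard statistics tooling.

## Reaction network

Edges are created by exact element-count arithmetic: f → g iff
g = f + Δ(t) for a catalog transformation t. This is deliberately stronger
than tolerance-based mass-difference matching — after assignment, formulas
are exact objects, so no mass window is needed and no false edges from
near-coincident deltas can occur. Parallel edges of distinct types are
kept; self-loops cannot occur (deltas are non-empty). Esterification applies
its delta (+SM − H₂O) wherever counts permit, at any oligomer size. The
catalog is user-extensible as a YAML file of signed element deltas. Networks
export as Cytoscape-compatible GraphML with formula/intensity/pagerank node
attributes.

## PageRank and Reverse PageRank

PageRank is computed by power iteration on the damped walk: a node's
transition mass is split over its out-edges proportionally to their
type weights (uniform by default), dangling nodes teleport uniformly,
d = 0.85 (the classic default; configurable), convergence at L1 residual
< 10⁻¹⁰, non-convergence raised with the residual attached. The test suite
verifies it against a dense linear solve of (I − d·M)π = (1−d)/N·𝟙.

Reverse PageRank infers type weights w ∈ [0.01, 1]^T from node intensities:
q = I/ΣI, minimize KL(q ‖ π(w)) (L2 and cosine objectives selectable). The
objective and optimizer are this package's own formulation of the
"edge probabilities from known scores" inverse problem; published
probability values obtained with other formulations need not be reproduced
numerically, which is why the optimizer reports its objective value and the
uniform-weight baseline for comparison. The search is derivative-free and
deterministic given a seed: cyclic coordinate refinement over a fixed grid,
a Nelder–Mead polish, and three seeded random restarts plus the uniform
start; the result can therefore never be worse than uniform weights. The
returned weights are normalized so the maximum is 1 (per-node edge
normalization makes π invariant to global weight scaling, so this is a pure
reparameterization). Every network node must carry a positive intensity;
missing intensities are an error, not imputed. Identifiability comes from
nodes with mixed out-edge types; a type that never shares a source node
with another type is constrained only weakly, which is the main caveat on
sparse networks.

## Synthetic data

The generator emulates the labeled chloramination experiment: a product
ensemble grown from C₇H₆O₃ by weighted random application of the
eight-reaction catalog (each step picks a random realized formula and a
transformation ∝ planted weights; a step completes when a new formula
appears; products violating the element limits are rejected, mirroring the
real experiment where out-of-limits species stay unassigned), rendered as
three technical replicates of deprotonated peaks with Gaussian m/z jitter
(σ = 0.2 ppm, the calibration-residual scale of well-calibrated FT-ICR
data), log-normal intensities (median 10⁸, σ_ln = 1, on the instrument's
arbitrary-unit scale), 10% per-replicate multiplicative scatter,
single-substitution isotopologue peaks at predicted shifts and ratios, 10%
per-replicate dropout, and Poisson contaminants (rate 0.05 per true
formula) at uniform random m/z — uniform mass defect, like the inorganic
background of real spectra. s2n is intensity divided by a 2·10⁵ noise
floor. Everything is reproducible from a single integer seed.

What the generator does *not* model: ionization efficiency and ion
suppression (intensities are treated as quantitative, the same assumption
the intensity-based analyses make), multiply charged ions, adducts,
double-isotope isotopologues (below the working intensity regime),
time-course kinetics, and bromine chemistry. Passing recovery tests on
synthetic data therefore demonstrates the correctness of the assignment and
network machinery under the stated noise model, not robustness to matrix
effects.

The amino-acid fixture defines the labeled validation mixture as the 20
canonical proteinogenic amino acids at equal intensity with all nitrogens
enriched. Leucine and isoleucine are constitutional isomers; their peaks
coincide exactly and merge, so the fixture's peak list has 19 monoisotopic
peaks covering 20 amino acids, and correct assignment of the shared
C₆H₁₃NO₂ peak validates both.

## Problem sizes and determinism

Default test and validation workloads are desk-scale by design: 1,000
random m/z for the enumeration oracle, 100 graphs ≤ 50 nodes for the
PageRank oracle, 20 simulated networks of 50–200 nodes for weight
recovery, and ~60-formula ensembles for the end-to-end recovery run. All
randomness flows through `numpy.random.default_rng` with explicit seeds;
re-running any pipeline command on identical inputs writes byte-identical
CSVs (stable sort orders everywhere, fixed print precision: 9 significant
digits for derived tables, 12 for peak lists, whose m/z round-trip must
stay below 0.01 ppm).
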