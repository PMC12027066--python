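# Methods

## The problem

Untargeted LCMS metabolomics detects thousands of peaks, most of which
cannot be assigned a compound identity from mass and retention time alone.
When cells are grown on a ¹³C-labeled nutrient, every downstream metabolite
inherits a characteristic mass isotopomer distribution (MID) — the vector
`x = (x₀, …, x_n)` of fractional abundances of its n+1 mass isotopomers —
determined by its biosynthetic route. Two biochemically related compounds
therefore have similar MIDs in *every* labeling experiment, and a compound
formed by joining two carbon skeletons has (approximately) the convolution
of its precursors' MIDs. `midtrace` exploits this to rank candidate
identities and discover biochemical relationships.

## The MID distance

For peaks A (m carbons) and B (n carbons, m ≤ n), every measured peak C
with n−m carbons is a candidate "convolutant" representing the carbon
moiety added in a pathway A + C → B. The distance is

    d(A,B) = min_C Σ_e ‖ x^{A,e} ⊛ x^{C,e} − x^{B,e} ‖₂

where `⊛` is discrete convolution, `(x⊛y)_k = Σ_{i+j=k} x_i y_j`, and the
sum runs over labeling experiments e. Conventions implemented here:

- **Equal carbon counts (m = n).** The only 0-carbon convolutant is the
  trivial MID `[1]`, so d reduces to the direct multi-experiment Euclidean
  distance. This is the natural limit of the formula.
- **Missing convolutant.** If no peak with n−m carbons exists, d(A,B) is
  set to the largest distance over all defined pairs (computed in a second
  pass) and the pair is flagged so evaluations can exclude it.
- **Missing experiments.** An experiment contributes to the sum only when
  A, B and C all have an MID there; each pair records the number of
  contributing experiments. Summing only over complete triples avoids
  fabricating zero differences. The sum is not divided by the number of
  experiments, so distances grow with panel size by design.
- **Uncorrected MIDs.** Distances are computed on MIDs *not* corrected for
  natural ¹³C; correction can push intensities negative and distort the
  convolution identity. Passing a corrected table emits a warning.
- **Ties.** Among convolutants with equal minimal distance the lowest peak
  id wins; neighbor lists break distance ties by peak id. All outputs are
  deterministic.

The distance is symmetric (the smaller peak always plays A) and
non-negative, but it is **not a metric**: the convolutant minimum violates
the triangle inequality, so clustering or embedding methods that assume
metricity should be applied with care. A small d(A,B) is necessary but not
sufficient for a biochemical relationship — convolutants can match by
chance, particularly for molecules of very different size or weak labeling.

`enrichment(x) = Σ_i i·x_i / n` is the fraction of a compound's carbon
atoms that are ¹³C. (An alternative reading, the fraction of molecules
with ≥1 ¹³C, is available as `mode="any_labeled"` for sensitivity checks.)

## Preprocessing

- **Natural-abundance correction.** With j tracer-labeled carbons of n, the
  remaining n−j positions each carry ¹³C with probability p₁₃ = 0.0107, so
  the measured MID is `M·x` with `M[k,j] = C(n−j, k−j) p₁₃^{k−j}
  (1−p₁₃)^{n−k}`. Correction solves the lower-triangular system exactly and
  falls back to non-negative least squares when noise drives components
  negative, then renormalizes. Only carbon is modeled; upstream peak
  detection is assumed to have resolved non-carbon isotopes (documented
  limitation).
- **Enrichment filter.** A peak is kept if its corrected enrichment is
  ≥ 10% in at least one labeled experiment (boundary inclusive); unlabeled
  control experiments are excluded from the maximum.
- **False-isotopomer filter.** A non-base mass isotopomer whose corrected
  fraction exceeds 0.03 in strictly more than 10 experiments is zeroed in
  all experiments (on the stored, uncorrected fractions) and the MIDs are
  renormalized; M+0 is never zeroed. Such isotopomers are almost always
  collisions with overlapping peaks rather than real labeling. Whether
  unlabeled controls count toward the 10 is configurable (default: yes).
  Both filters are idempotent and their order (enrichment first) is
  recorded in the filter report.
- **Co-elution grouping.** In-source fragments and adducts co-elute with
  their parent and share its labeling. Peaks within `rt_tolerance` (default
  5 s) *and* with MID distance < `d_cutoff` (default 0.3) are grouped by
  single linkage; the representative is the member with the most carbons
  (ties: lowest id). Co-eluting peaks with dissimilar MIDs stay separate —
  distinct labeling rules out a shared source molecule. The two defaults
  are instrument- and data-dependent and are exposed in configuration.

## Network simulation (EMU)

Atom-mapped networks are parsed from a plain-text reaction format with
per-carbon letter mappings (reversible reactions appear as two opposing
irreversible ones; a reaction with no products is a sink; substrates are
external sources with tracer-defined labeling). Validation enforces that
every product carbon has exactly one reactant source and that production
equals consumption at every non-substrate metabolite (relative tolerance
1e-9).

The network is decomposed into elementary metabolite units (EMUs) by
backward tracing from the full-carbon EMUs of the target metabolites;
condensations yield EMU reactions whose source MIDs convolve. Labeling
dynamics follow, per mass isotopomer of each EMU of metabolite M,

    dX_E/dt = (1/pool_M) Σ_r v_r (S_r − X_E)

with S_r the source MID (or convolution) of producing EMU reaction r. All
EMUs start unlabeled `[1,0,…,0]`; substrate EMUs are fixed by the tracer
(labeled fraction and per-position purity; purity defaults to 1 and natural
abundance is *not* added to simulated data — the simulation study is about
the distance, not instrument realism; a flag can apply the forward
correction model). The stiff-capable LSODA integrator is used with
rtol 1e-8 / atol 1e-10 on a 200-point log-spaced grid; the grid horizon
defaults to `(20 + 3·n_metabolites) × max(pool/consumption)`, which covers
steady state for the bundled networks. Steady-state MIDs solve the same
balances as linear systems block-by-block in EMU size (convolution sources
are always strictly smaller, so each block is linear given the previous
ones); a singular block names the metabolite without a production path.

**Pre-steady-state sampling.** Batch labeling experiments rarely reach
isotopic steady state, so panels are sampled at a fraction (default 0.5) of
t_ss, the earliest grid time at which the largest |dMID/dt| falls below
1e-6 per time unit. Pool sizes are not observable from flux data and
default to 1; only pool/flux ratios shape the transients (uniform scaling
of all fluxes and pools rescales the time axis and nothing else).

## Biochemical relatedness f

The gold standard for evaluation is the fraction of carbon one metabolite
derives from another. To compute the contribution of A to B, A is turned
into a network substrate — which removes the isotope-label contribution of
every reaction producing A while leaving all fluxes at the same flux state —
A's pool is fixed fully labeled, and the steady-state enrichment of B is
read off. f(A,B) is the larger of the two directional contributions
(f(A,A) = 1), and pairs with f > 1/2 (strict) are labeled biochemically
related. One network surgery and one steady-state solve per source
metabolite yields the full matrix in O(n) solves. f is invariant to uniform
flux scaling, and on carbon-preserving linear pathways every
upstream–downstream pair has f = 1.

## Evaluation design

Precision-recall against the f > 1/2 labels sweeps the distance threshold
over all unique values; AUPR integrates precision over recall by trapezoids
with an initial point at (0, precision of the smallest threshold).
Missing-convolutant (sentinel) pairs carry no ranking information and are
excluded from the sweep and from prevalence (a flag ranks them last
instead); incomparable pairs (no shared experiment) are always excluded.
Robustness analyses re-draw Gaussian MI noise (clip at 0, renormalize) or
random metabolite subsets per replicate from seeded generators;
discoverability asks whether ≥ half of a metabolite's true partners appear
among its 20 nearest neighbors; greedy tracer selection adds, at each step,
the experiment maximizing AUPR recomputed from scratch on the grown subset
(ties to the lexicographically smaller name). The noise model — additive
independent Gaussian on MI fractions, clipped and renormalized — is an
assumption; instrument noise is in reality intensity-dependent.

## The synthetic evaluation network

The default fixture (`eval_default`, 24 metabolites, 5 tracers) emulates a
minimal anabolic system: five substrates (glc 6C, ala 3C, gly 2C, asp 4C,
met 5C) feed carbon-preserving transformation chains (glucose four deep,
the others three), a cleavage splits the three-carbon intermediate p2 into
2C + 1C products (ace, fmt), and one condensation joins two one-carbon
units (x1), exercising the convolutant search, cleavage EMUs and
convolution EMUs. Fluxes are back-propagated from unit sink demands so
every reaction is active at comparable magnitude.

Two pool-size choices matter and are deliberate:

- Pathway intermediates share a common slow relaxation time (pool 40000 at
  unit flux). Sampling at half of t_ss (with the 1e-6 rate tolerance) then
  leaves labeling deficits between ~0.03 and ~0.6 — genuinely mid-transient
  MIDs, orders of magnitude above integrator error, with gap structure at
  the scale of the benchmarked noise levels (0.005–0.02) so that noise
  erodes the ranking progressively rather than all at once.
- Cleavage/condensation products get 10× smaller pools (low-abundance
  species), so they track the quasi-steady convolution of their precursors —
  the regime in which the convolution distance is informative.

On this fixture the direct biosynthetic precursor is the single nearest
neighbor for 18 of 19 non-substrate metabolites; the exception is fmt,
whose nearest neighbor is its own condensation product x1 — an instructive,
realistic failure: a fast downstream conjugate can resemble its precursor
more than the precursor's own parent does. Designs in which conjugates
condense two *substrate* moieties were rejected during development: a
substrate's MID is a constant delta, so such conjugates equal exact
convolutions of constants and generate degenerate zero-distance unrelated
pairs (and equal-by-construction "twin" distances) that dominate the top of
the ranking; parallel branches with similar turnover were likewise rejected
because their labeling curves cross, again producing near-zero unrelated
pairs.

What passing tests on this fixture shows — and what it does not: the
distance, simulation, gold standard and metrics are internally correct and
behave as designed under controlled labeling kinetics, sparse relatedness
and Gaussian noise. The fixture does not emulate real LCMS data (no
peak-detection artifacts, no intensity-dependent noise, no isobaric
overlaps, no missing convolutant classes), so performance numbers on it are
properties of the design, not predictions for any particular instrument or
organism.

## Numerical choices and degenerate inputs

- MIDs must be non-negative and sum to 1 within 1e-9; normalization clips
  negatives only below a small tolerance and rejects anything larger. An
  all-zero intensity vector raises an "empty MID" error rather than
  silently producing a vector of zeros; a missing MID is an absent entry,
  never an all-zero one.
- Convolutions renormalize their output to remove accumulated rounding, so
  `sum(a⊛c) = 1` holds exactly.
- Distances are double precision; package tests compare the optimized
  pairwise path against a naive exhaustive search for exact equality.
- Zero-carbon species (e.g. untracked cofactor stubs) are carried with the
  trivial MID `[1]` and never enter enrichment or distance computations.
- Zero pool sizes are rejected; metabolites with zero production flux are
  reported by name when a steady-state block is singular.

## Known limitations

- Only carbon is traced; multi-element tracers and non-carbon natural
  isotopes are out of scope.
- No raw LCMS processing: MID tables are the entry point.
- Candidate annotation replaces expert "structural similarity" judgment
  with user-supplied structure-class tags — reproducible and auditable, but
  only as good as the tag vocabulary; no chemical-similarity engine and no
  MS² evidence are included.
- The stated flux state is taken as given; no flux estimation is performed.
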