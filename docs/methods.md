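# Methods

## Model and procedure

The package scores the structural divergence between a wildtype protein model
and a mutant model of identical length.  The pipeline is:

1. **CA extraction** (`structio.read_ca_trace`).  Only alpha-carbon
   coordinates are used.  Residues are matched strictly by position on
   equal-length traces; no sequence alignment is attempted, because the
   method addresses substitutions, which preserve length.  A length or
   position mismatch is an error, not a warning — silently aligning two
   different constructs would invalidate every downstream quantity.
2. **Superposition** (`structio.superpose`).  A least-squares rigid-body fit
   (Kabsch, via SVD with reflection correction) over *all* matched CA atoms.
   No iterative outlier trimming is done: a global fit is reproducible,
   order-independent, and makes the per-residue deviations A_i directly
   comparable across mutants of the same protein.  The overall RMSD r̄ is the
   population RMS of the A_i.
3. **Scoring** (`scoring.final_score`) over a set of 1-based, inclusive,
   non-overlapping domain intervals — ideally the functionally critical
   domains of the protein.  Consecutive non-overlapping residue pairs
   contribute an observed term (A_i + A_{i+1})/N and a background term
   m·r̄/N (m = 2 for a full pair, 1 for the degenerate (j, j) pair that closes
   an odd-length domain, whose A-value is counted twice in the pair mean).
   The raw score Γ projects ISF + B onto the ISF direction and halves it; the
   significance coefficient κ ∈ [0, 1] compares the signal excess Σδ with a
   Gaussian order-statistic term Σγ; the final score is Γ·κ.
4. **Interpretation** — either ordinal classification against
   control-derived thresholds (`interpret`), or correlation with measured
   residual enzyme activity plus trendline prediction (`correlate`), with
   optional per-residue weight training (`optimize`).

### Assumptions

- Both models come from the *same* modelling procedure; the score measures
  divergence between them, so systematic server-to-server differences are
  confounded with mutation effects.  Control scores (wildtype vs refined
  wildtype) anchor the scale for exactly this reason.
- The per-residue deviations are treated as approximately Gaussian when
  computing Σγ; this is a heuristic significance term, not a calibrated test.
- The score is relative.  Absolute values depend on the modelling pipeline
  and are meaningful only against controls computed the same way.

## Numerical choices

- **Weight/conservation normalisation.**  Both vectors are divided by their
  mean over the union of scored domains before use.  This is the minimal
  mechanism that makes the documented invariance — multiplying either file by
  a positive constant leaves the score unchanged — literally true, including
  for κ, whose Σγ term carries no weight/conservation factor.  The defaults
  (weight 10, conservation 1) both normalise to all-ones, so supplying no
  files is identical to supplying uniform ones.
- **Pair-level scores** are the arithmetic mean of the two residues' values:
  symmetric, and identical to the per-pair-start convention for uniform
  vectors.
- **Z-argument clamp.**  γ uses Z(1 − L/N) with the argument clamped to
  [1/(N+1), N/(N+1)] (the standard plotting-position bounds) so a
  whole-protein domain (x = 0, Z = −∞ otherwise) stays finite.
- **Degenerate κ.**  When Σδ = Σγ = 0 (e.g. a uniform-deviation profile),
  κ := 0.5, the symmetric value, so the negative-control identity
  final = Γ/2 holds continuously.  Two float-exactness guards support this:
  the background term is computed as (m·r̄)/N so that ISF and B are
  bit-identical for uniform deviations, and the population SD of a constant
  deviation vector is forced to exactly 0 (`np.std` returns ~1 ulp of the
  mean there).
- **Threshold reading.**  The classification threshold from controls
  (anchor M = (S_C + (2·S_K + 3.24·S_C)/5.24)/2, spread σ = two-value sample
  SD) is exposed in two modes: `additive` (default), T1 = M + 3·(K/100)·σ,
  which matches the bracket construction around an anchor; and `product`,
  the literal printed product, which collapses to zero width at σ = 0.
  Classification boundary ties resolve to the lower (less deleterious)
  category.
- **Stringency-sweep p-value.**  The sweep reports the one-sided binomial
  tail probability of the observed number of correct calls under a 50%
  guessing null.  The per-trio spread uses σ(S_C, S_K) — negative vs positive
  control — since a trio carries no intermediate score.
- **One-tailed correlation p** is the tail of t = r·√((n−2)/(1−r²)) with
  n−2 degrees of freedom on the side of the observed sign; r = 0 gives
  exactly 0.5.
- **Outlier exclusion** is a single pass: means and sample SDs (n−1) over all
  input points, exclusion iff strictly beyond k·SD (default k = 2) in either
  coordinate.  No re-iteration; a re-iterated rule would make the kept set
  depend on exclusion order.
- **Prediction accuracy.**  Because "percent accuracy" of an activity
  prediction is ambiguous, the primary metric is the mean absolute error in
  activity-percent; a secondary derived metric 100·(1 − MAE/mean(observed))
  is reported under that explicit name.

## Weight training

`train_weights` is a seeded greedy hill climb: per round it proposes a weight
vector — by default resampling a fraction (0.1) of coordinates uniformly in
[0, 10], alternatively resampling the whole vector — rescores every profile
with the shared candidate, and accepts iff the Pearson correlation with the
activities strictly improves (becomes more negative).  The best-so-far trace
is therefore monotone and the run bit-reproducible for a fixed seed.  The
panel is evaluated through a vectorised fast path (pair sums, background
multiplicities and Σγ precomputed once); its agreement with the scalar
scoring chain is unit-tested.

**Identifiability.**  With N free weights and K < N profiles, the training
objective is degenerate: any activity vector can be interpolated exactly
(r = −1) and the recovered weights are arbitrary off the causal region.  Real
enzyme panels (8–20 mutations, hundreds of residues) are in this regime, so
training there is score *sharpening*, not region *discovery* — improved
correlation on the training panel must not be read as localisation evidence.
The synthetic training panel (`make_training_panel`) therefore defaults to
the identifiable regime: 400 profiles of 120 residues, baseline half-normal
model noise of 0.4 Å, a planted causal window at residues 40–60 (activity =
100 − 30·amplitude + N(0, 2)) and an uncorrelated distractor at 80–100.
Under those conditions training reliably recovers the causal window
(top-decile weights concentrate there), which is what the planted-recovery
check certifies.

## Synthetic data

`make_backbone` produces an ideal α-helical CA trace (rise 1.5 Å/residue,
radius 2.3 Å, 100°/residue): a well-conditioned, interpretable geometry for
superposition, unlike a random coil.  `perturb` displaces only a residue
window, either by isotropic Gaussian jitter (per-coordinate SD = magnitude/√3,
giving a chi-3 mean displacement of ~0.92·magnitude) or by a rigid hinge
rotation calibrated to the requested mean displacement.  `make_activity_panel`
couples planted magnitude to activity at 20 %/Å with Gaussian measurement
noise (default SD 5), floored at 0, on the 0–100% scale of experimental
residual-activity tables.

What this emulates is the *displacement field* a modelling server produces
for a point mutation: localized, magnitude-controlled, on a shared backbone.
What it does not emulate: secondary-structure rearrangement, compaction,
server stochasticity between submissions, or global refolding.  Passing tests
therefore certify the arithmetic chain and its statistical behaviour on
localized perturbations — not predictive accuracy on real modelling-server
output, which additionally depends on model quality.

## Problem sizes

The default test and acceptance runs use: 100 random 5–50-residue instances
for the superposition oracle; 100 random 80-residue profiles for
homogeneity; 10,000 draws for the κ bounds; 10 panel seeds × 4000 training
rounds (single-coordinate proposals) for planted recovery; and 20 seeds × 4
magnitudes at N = 100 for end-to-end monotonicity.  These sizes give stable
statistics while keeping the full suite in the tens of seconds on one CPU.

## Known limitations

- Absolute score parity with other implementations of the same formulas
  cannot be certified: published absolute scores depend on external
  server-generated models and unspecified superposition details.  Parity is
  claimed for the documented formulas and their invariants only.
- The stringency→threshold formula's printed worked value could not be
  reproduced under either reading; the formula is exposed with both readings
  and the classification logic is certified against a directly supplied
  threshold instead.
- Gain-of-function semantics (negative weights) are not defined.
- Only PDB input (first MODEL, ATOM records) is supported; mmCIF is not.
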