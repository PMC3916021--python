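# Methods

## Problem and pipeline

The package derives a two-sided gene signature that separates ER+ from
ER− breast cancer samples, treating the interaction network itself as an
unreliable measurement. The stages are:

1. **Network construction.** Multi-source interaction records are
   deduplicated into an undirected simple graph; self-interactions are
   dropped and each edge keeps the union of the databases (sources) and
   experimental methods that reported it. Gene identifiers are opaque,
   case-sensitive strings; mapping proteins to genes is assumed done
   upstream.
2. **Reliability scoring.** Per edge: R₁ = source count, R₂ = method
   count, R₃ = combined level-2 neighbour count of the two endpoints.
   Each measure is min–max rescaled to [0, 1] over the whole network and
   combined as μ = β₁r₁ + β₂r₂ + β₃r₃ with fixed published coefficients
   (0.7138, 0.2912, 0.3072; intercept 0). The original coefficients came
   from a regression whose response variable is not recoverable, so they
   are treated as configuration — the published operating point — rather
   than re-fit.
3. **Expression preparation.** Each dataset is min–max rescaled per gene
   to [0, 1] *before* integration; integration intersects gene sets (no
   imputation) and concatenates samples. Optional probe-level input is
   collapsed by dropping `AFFX` control probes and keeping the
   highest-variance probe per gene (a documented stand-in for the
   original probe-collapse procedure, which is delegated to a citation;
   per-gene mean is available as an alternative). Samples missing ER
   status or grade are excluded; the rest partition into the six
   (ER±) × (grade 1/2/3) training sets.
4. **Reliable expression.** Per stratum: G(a) is the quadratic mean of a
   gene's values over the stratum's samples (the printed formula omits
   the root, but "generalized mean" plus the requirement that a constant
   profile summarise to itself force the power mean of order 2);
   σ(y) is the harmonic mean of the endpoint G values, zero if both are
   zero, and edges with an unmeasured endpoint are excluded from that
   stratum rather than imputed. δ = sign((μ−μ̄)(σ−σ̄)) with the means
   taken over the stratum's measured edges; the printed δ ratio is read
   as a sign because its stated codomain is {−1, 0, +1}. For δ = +1
   edges, θ = β₁μ + β₂σ with per-stratum published coefficients
   (ER+ grades 1–3: (0.4601, 0.7066), (0.4878, 0.6846), (0.4650, 0.7094);
   ER− grades 1–3: (0.4273, 0.7274), (0.4484, 0.7199), (0.4673, 0.7078);
   intercepts numerically zero and fixed at 0).
5. **Significance.** The per-interaction p-value is not defined in the
   source description; it is implemented as an upper-tail z-test of θ
   against the stratum's positive-edge θ distribution (population sd),
   threshold α = 0.05 (configurable). This selects the high-θ — jointly
   reliable and expressed — tail, which is what the downstream algorithm
   consumes, and calibrates exactly to the nominal level under an i.i.d.
   null (verified at 10,000 edges).
6. **Subnetwork selection.** Significant edges form a graph whose
   connected components are subnetworks. λ sums θ over a component's
   edges; hubs are all maximum-degree genes (ties kept); χ is a hub's
   mean incident θ and a component's χ is the max over its hubs. The
   maximum-λ component is admitted whole (tie-break: larger gene count,
   then smallest gene id — determinism); every other component with
   χ *strictly* greater than the chosen component's χ contributes its
   hub(s) plus their direct interactors, read literally from the rule's
   "hub-gene with their interactors".
7. **Signature assembly.** Per ER side, genes present in all three grade
   lists are the side's common genes (a 2-of-3 or 1-of-3 threshold is
   exposed); genes common to both sides are removed from *both*, which
   yields the disjointness the published 326/145 split implies.
8. **Classification.** Samples map to (S₊, S₋) — mean normalised
   expression over each side's measured signature genes, the divisor
   adapting to platform gene loss — and are classified by 3NN majority
   under L1 distance. The reference set is all pooled training samples
   (the only labelled set available; the original choice is unstated).
   Neighbour ties at the k-th distance break by (distance, reference
   index) stable sort. MCC uses the convention that any zero marginal sum
   sets the denominator to 1, giving MCC 0; report rounding is 3
   decimals, ties away from zero.

## Synthetic studies

The generator emulates the structure of the real inputs, not their scale:

- **Network**: `n_genes = 200` over 6 sources and 5 methods; background
  pairs appear with probability 0.02 and carry light evidence (1–3
  sources/methods); a fraction `fp_edge_fraction = 0.1` of them get
  exactly one source and one method — the false-positive profile is
  modelled purely as minimal evidence, since evidence counts are all the
  method can see. Two planted 10-gene modules (one per ER side) are wired
  as a connectivity-guaranteeing ring plus random pairs at density 0.6,
  with rich evidence (4–6 sources, 3–5 methods).
- **Expression**: each gene has a fixed baseline drawn uniformly on
  [0, 1]; planted-module genes gain `expression_shift = 0.5` in samples
  of their module's ER side across all three grades; Gaussian noise with
  `noise_sd = 0.05` is added per sample and values are clipped to [0, 1].
  Baselines are per-gene constants (not i.i.d. per cell) so genes have
  characteristic levels and the per-dataset rescaling step is exercised
  nontrivially; 20 training samples per stratum are split round-robin
  over two dataset ids, and 30 held-out test samples per ER class form
  their own dataset. A `raw_scale` mode applies a per-dataset affine
  distortion so the rescaling is tested away from near-identity.
- **Determinism**: one pseudo-random stream per stage, spawned from the
  master seed, so the same seed gives byte-identical files and stages can
  be regenerated independently.

What passing synthetic tests shows: the pipeline's selection logic
(reliability weighting, positive-correlation filtering, significance
tail, hub rules, cross-side deduplication) recovers planted differential
modules and rejects minimal-evidence and non-differential edges under
realistic noise. What it does not show: performance on real microarray
cohorts — the generator has no batch effects, probe saturation,
platform-specific distributions, correlated background expression or
survival structure, and its effect sizes are planted, not biological.
The published real-cohort headline numbers (e.g. MCC 0.868/0.692)
require the original database snapshots; here they are validated only as
arithmetic from their printed confusion counts.

## Numerical choices and degenerate inputs

- Min–max rescaling with a zero range (constant measure or feature) maps
  to 0 everywhere: an uninformative measure confers no credit.
- θ spread below float round-off of the values (sd ≤ 1e-12 × max |θ|)
  counts as zero spread: no edge significant.
- σ with G(a)+G(b) = 0 is defined as 0; records without a method label
  pool into one reserved `unknown` method and count once.
- Strata with no samples, no positive edges or no significant edges
  propagate as empty outputs with warnings; the pipeline only fails if
  *both* final signature sides are empty.
- Problem sizes used by the test suite and the acceptance script
  (200-gene networks, 120-sample training cohorts, 60-sample test
  cohorts, 10 seeds, 10,000-edge null) are chosen so a full run completes
  in seconds while leaving all selection steps non-trivial.

## Known limitations

- The regression steps behind μ and θ are frozen at their published
  coefficients; re-fitting to a user's own compendium is out of scope.
- No multiple-testing correction is applied to the per-edge significance
  filter (none is applied in the source procedure either); α is the
  per-edge level.
- Signature assembly assumes three grade lists per ER side; other
  stratification schemes would need a different commonality rule.
- Survival metadata is carried through but not analysed.
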