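# Methods

## Screen model and data layout

The unit of data is a well on a 384-well plate, annotated with screen,
plate, replicate, siRNA, gene, role and stimulus, and carrying two
non-negative readouts: a reporter channel (luciferase RLU or QUANTI-Blue
absorbance) and a viability/transfection channel (β-gal ABS405 or XTT).
Tables are long-format TSV (one row per well) because replicates and dual
stimulus arms do not fit a plate matrix. Control wells (non-targeting,
pathway-positive p65, receptor-positive NOD1, toxicity PLK) carry an empty
`gene_id` and never enter gene-level scoring. Every plate is expected to
carry all four control roles; the layout validator checks presence only,
since physical control positions are not part of the contract.

## QC and normalization cascade

Order matters and is fixed: plate-level exclusion strictly precedes
well-level exclusion, so a well on a failed plate carries the reason
`plate_failed` only.

* **Plate QC.** A plate fails when the mean viability readout of its
  non-targeting controls is above 2.5, below 0.2, or when their SD/mean
  exceeds 0.50. The "SD > 50%" rule is implemented as a coefficient of
  variation: an absolute SD cutoff of 0.5 would be unsatisfiable jointly
  with the 0.2 lower mean bound. All three reasons are evaluated
  independently and may co-occur. At least two non-targeting wells are
  required; fewer is an error, not a pass.
* **Well filter.** On passing plates, wells with viability strictly below
  40% of the plate's non-targeting-control mean are excluded; controls are
  subject to the same rule; a well exactly at the boundary is kept
  (strict inequality as specified).
* **Activity ratio.** reporter / viability per well (nRLU, nQB). The ratio
  is undefined (error) at zero viability; such wells are excluded by the
  40% rule first in practice.
* **NPI.** `(μ_neg − x) / (μ_neg − μ_pos)` with per-plate control means
  computed from wells surviving the viability filter. NPI is invariant
  under rescaling a plate's activities by a common positive factor, which
  is what cancels multiplicative plate effects. The positive anchor is the
  p65 pathway control in the HEK screens and the NOD1 receptor control in
  the THP1 screen (where NOD1 is the endogenous receptor driving the
  readout). Computed per plate, not per run.
* **z-scores.** Per replicate plate, centered to the *median* of the
  non-targeting controls' NPI; the scale is 1.4826 × MAD of the plate's
  sample NPIs by default. Only the centering is externally fixed; the
  scale estimator is a design choice and is configurable
  (`zscore_scale: sample_mad | neg_sd`). The sample-MAD default is robust
  to the fraction of true actives and does not degenerate on plates with
  few controls. z-scores on NPI are inhibition-positive, so no sign flip
  is needed; the orientation string is recorded in the score-table
  metadata. The per-siRNA screen score is the median z over surviving
  replicates (z per plate first, then median — not median-then-z), with
  `n_replicates_used` recorded; an siRNA with no surviving replicate is
  emitted with a missing score and is not ranked.

Degenerate inputs raise typed errors rather than propagating NaN: equal
control means (NPI undefined), zero scale (a literally noise-free plate),
insufficient controls.

## RSA gene scoring

siRNAs are ranked screen-wide by oriented median z (rank 1 = strongest
inhibition). Exact ties take the worst rank of the tied block —
conservative, since optimistic tie placement would inflate gene scores;
residual exact ties within one gene are spread deterministically over the
block's worst positions. For a gene with k of N ranked siRNAs at ranks
r₁ < … < r_k:

    p_min = min_j P(X_j ≥ j),  X_j ~ Hypergeometric(N, r_j, k)

computed as an exact survival sum (no normal approximation; N is small
enough that exactness is cheap). The minimizing j (smallest j on ties)
defines the cutoff rank; the gene's siRNAs at or above it are its OPI
hits; genes with fewer than two OPI hits are flagged and dropped from the
hit list (retained, flagged, in the full output). Genes are ranked by
ascending log₁₀ p, ties broken by best siRNA rank then gene id. No
multiple-testing correction is applied: the output is a ranking, and p_min
— a minimum over dependent tails — is anti-conservative as a p-value
(measured inflation ≈ 3α under a null screen; see the calibration test).

**Hit-zone restriction.** `gene_logp` by default minimizes over all
cutoffs j = 1..k. The pipeline additionally restricts cutoff candidates to
siRNAs inside the screen's hit zone (score > non-targeting median + 2
control SDs, the same SD-margin construction the triage rules use). The
unrestricted minimum lets a gene whose only real signal is one strong
siRNA "borrow" support from chance mid-ranking placements of its other
siRNAs (with k = 4 and three null siRNAs, the joint tail beats the
single-siRNA tail in roughly a quarter of cases), which defeats the
purpose of the <2-OPI-hit off-target filter. Restricting cutoffs to actual
hit-siRNAs makes the OPI count mean what it says. Both behaviours are
exposed; the contract-level examples and the enumeration oracle use the
unrestricted form.

## Triage rules

All secondary-screen rules are strict SD margins over the non-targeting
control z-score distribution *of the same screen arm* (median and SD of
surviving control wells' z):

* validation (elicitor arm, two re-synthesized siRNAs per gene): siRNA hit
  iff z > median + 2·SD; gene hit iff its strongest siRNA qualifies. The
  strongest-siRNA gene rule matches ranking the validated list by the
  strongest siRNA; requiring both siRNAs is available via
  `gene_hit_rule: both`.
* counter screen (TNF arm): same rule; hits are pathway-nonspecific and
  excluded.
* THP1: gene hit iff ≥2 siRNAs exceed 1.5·SD; strong hit if additionally
  ≥1 siRNA exceeds 3.0·SD (strong ⊂ hit by construction). Genes with
  fewer than two scored siRNAs are flagged insufficient-data.
* final shortlist = (validation ∩ THP1) \ counter-screen exclusions. All
  subset invariants are enforced by the `TriageResult` type itself.

In the end-to-end pipeline the candidate list is the top 6.2% of the
RSA-ranked gene universe (the ratio of a ~435-gene candidate list to a
~7000-gene library), and each candidate enters the secondary screens with
its two strongest primary-screen siRNAs. The secondary calls re-use the
simulated screens' replicate z-scores for those siRNAs rather than
simulating a separate re-synthesis round; the rule functions accept any
siRNA z table, so an independently simulated (or real) validation screen
can be substituted.

## Synthetic screens

The generator emulates the screen design: genes × 4 siRNAs, quadruplicate
HEK elicitor and TNF counter arms, triplicate THP1 arm, every plate
carrying 6 non-targeting, 4 p65, 3 NOD1 and 3 PLK control wells.
Per well:

    t ~ LogNormal(mean 1, CV 0.20)          transfection efficiency
    v = t · (1 − toxicity loss)
    viability readout  = plate_factor · v · ε_b
    activity readout   = plate_factor · t · baseline · (1 − e) · ε_a

with ε mean-1 lognormal (CV 0.15 per channel), plate_factor mean-1
lognormal (CV 0.15), and inhibition e combining on-target knockdown with
planted off-target effects as 1 − (1−e_on)(1−e_off). Lognormal
multiplicative noise reflects positive, multiplicative-error instruments.
The TNF arm responds only to the shared-pathway subset of inhibitors
(default 20%); p65 controls inhibit in all arms, NOD1 controls only under
the elicitor, PLK controls lose ~97% viability.

Desk-scale defaults: 500 genes, 25 planted inhibitors with effects drawn
uniformly from [0.70, 0.95] on all four siRNAs, ten decoy genes carried by
exactly one strong (0.8) off-target siRNA, 1% toxic siRNAs and 0.5% extra
off-targets planted only on genes that are neither inhibitors nor decoys
(keeping the truth classes disjoint and attributable), control knockdowns
0.90 (p65) and 0.85 (NOD1). Control effect sizes are package defaults, not
values inferred from any particular assay. A full-scale preset (7000
genes) scales the same design. The 500-gene desk scale (~23k wells,
seconds per run) is the size at which every property of the method is
already exercised — plate structure, replicate aggregation, rank
granularity of 2000 siRNAs — and is the size used throughout the tests
and the acceptance script.

Randomness: one root seed; the truth tables and every plate draw from
documented child streams `default_rng([seed, stream_id])`, so identical
(config, seed) gives bit-identical TSV output and single plates are
reproducible in isolation.

What the generator does *not* model: spatial (edge/row) plate effects —
the pipeline deliberately applies no spatial correction, so simulating
them would only demonstrate a known blind spot; siRNA sequence features or
seed-region off-target prediction (off-targets are planted abstractly);
cell-line-specific effect differences between the HEK and THP1 arms
(inhibitors act identically in both, so cross-cell-line confirmation in
the simulation is optimistic relative to real screens); and correlated
reagent batch effects. Passing recovery tests therefore show the
statistical machinery is correct under the stated error model, not that
real screens of this design will achieve the same sensitivity.

## Numerical and design notes

* Thresholds all live in one `Thresholds` object (2.5 / 0.2 / 50% / 40% /
  2.0 / 1.5 / 3.0 defaults); stage logic never hard-codes them.
* Well coordinates "A01".."P24", parsed case-insensitively.
* Boundary behaviour is strict everywhere, exactly as the rules are
  phrased: mean exactly 2.5 passes, viability exactly 40% is kept,
  z exactly at margin is not a hit.
* Gene-level p is computed with `scipy.stats.hypergeom.sf`; equality with
  brute-force enumeration over all C(N,k) placements is tested
  exhaustively for N ≤ 12, k ≤ 4 at 1e-12.
* The null-calibration test pools 20 simulated null screens of 200 genes
  (k = 4) and checks the fraction of genes with p_min < 0.05 stays below
  6 × 0.05, a bound chosen with headroom above the measured ≈ 3×
  inflation of the min-over-cutoffs statistic.
* Pipeline runs are reproducible from (config, seed); the run manifest
  records the config digest, seed, version and timestamps. Data artifacts
  are byte-identical across reruns; the manifest's timestamps are the
  only exception.

## Known limitations

* p_min is a ranking statistic, not a calibrated p-value; do not threshold
  it for discovery control.
* The validation/counter/THP1 layers of the bundled end-to-end pipeline
  share the simulated screens' scores with the primary screen (see above);
  hit-count attrition between layers is therefore milder than in a real
  two-round design.
* A literally noise-free screen has zero sample MAD and no defined
  z-scores; the degenerate-scale error is raised by design. Ordering
  properties in that limit are tested with vanishingly small (1e-9) noise.
* With `gene_hit_rule: strongest`, a single strong off-target siRNA can
  pass the validation layer; the RSA OPI filter upstream is the off-target
  defence.
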