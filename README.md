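# rnaiscreen

Hit-calling pipeline for arrayed, dual-readout siRNA screens.

In an arrayed RNAi reporter screen, each well of a 384-well plate receives
one siRNA, a pathway stimulus, and two readouts: a reporter channel
(NF-κB–driven luciferase RLU, or SEAP read as QUANTI-Blue absorbance) and a
viability/transfection channel (β-galactosidase ABS405, or XTT). Turning
tens of thousands of such wells into a defensible gene list requires a
chain of statistical steps — plate-level quality control, well-level
toxicity filtering, normalization that cancels plate effects, robust
scoring, gene-level aggregation over redundant siRNAs, and multi-screen
triage against counter-screens. `rnaiscreen` implements that chain as a
tested Python library with a thin CLI, plus a seeded synthetic-screen
generator with known ground truth so the entire pipeline can be exercised
and benchmarked without any external data.

It is intended for computational biologists analysing (or planning)
arrayed knockdown screens, and for anyone who wants a reference
implementation of redundant-siRNA-activity gene ranking with a controlled
simulation harness.

## The analysis chain

1. **Plate QC** — a plate is discarded when the mean viability signal of
   its non-targeting controls is > 2.5 or < 0.2, or their coefficient of
   variation exceeds 50%.
2. **Well viability filter** — wells below 40% of the plate's
   non-targeting-control mean viability (toxic siRNA or failed
   transfection) are excluded; boundaries are strict.
3. **Normalization** — activity ratio nRLU = RLU/ABS405 (or nQB = QB/XTT),
   then normalized percent inhibition
   `NPI = (μ_neg − x) / (μ_neg − μ_pos)`, anchored per plate at the
   non-targeting (0) and pathway-positive (1) control means.
4. **Robust z-scores** — per replicate plate,
   `z = (NPI − median(NPI_neg)) / (1.4826 · MAD(NPI_samples))`, then the
   median z across replicates per siRNA. Larger positive z = stronger
   inhibition.
5. **RSA gene ranking** — with N ranked siRNAs overall and a gene's k
   siRNAs at ranks r₁ < … < r_k,

   ```
   p_min = min_{j=1..k}  P(X_j ≥ j),   X_j ~ Hypergeometric(N, r_j, k)
   ```

   reported as logP = log₁₀(p_min). The minimizing cutoff defines the
   gene's "OPI hits"; genes with fewer than two are dropped as probable
   single-siRNA off-target artifacts. The pipeline restricts cutoff
   candidates to siRNAs inside the screen's hit zone (scores more than
   2 SD above the non-targeting-control median).
6. **Triage** — validation-screen call (strongest siRNA > 2 SD over the
   control median), TNF counter-screen exclusion of pathway-nonspecific
   genes, THP1 dual-readout call (two siRNAs > 1.5 SD; strong hits
   additionally one siRNA > 3 SD), and the cross-cell-line intersection
   that yields the final shortlist.

The synthetic generator plants inhibitor genes, toxic siRNAs, off-target
decoys and multiplicative plate effects with a per-plate seeded RNG, and
`evaluate_recovery` scores how well the pipeline recovers the planted
truth.

## Worked example

Run the full desk-scale study (500 genes × 4 siRNAs, quadruplicate HEK
elicitor + TNF arms, triplicate THP1 arm — 66 plates, ~23k wells):

```sh
rnaiscreen all --outdir demo_run --seed 1
```

This writes the simulated well table, QC and normalization artifacts, the
RSA gene list and the triage tables, ending with `flow_report.txt`:

```
screening flow (genes per stage)
-----------------------
primary_ranked      25
validation_hits     25
nod1_specific       20
thp1_hits           25
thp1_strong         25
confirmed_both      25
final_shortlist     20
```

All 25 planted inhibitor genes survive RSA ranking and both validation
layers; the 5 planted inhibitors that also act on the shared (TNF) arm are
correctly removed by the counter screen, leaving the 20 pathway-specific
genes. The top of `gene_ranked.tsv`:

```
gene_id  k  best_rank  log_p    opi_hit_count
G0074    4  1          -11.109  4
G0243    4  3          -9.963   4
G0240    4  13         -8.031   4
```

A gene whose four siRNAs land at screen ranks 1, 2, 4 and 5 of 2000 gets
logP ≈ −11: the probability that randomly placed siRNAs cluster that
tightly at the top. All ten planted decoy genes — carried by a single
strong off-target siRNA each — are removed by the <2-OPI-hit filter.

The same pipeline stages are importable as library functions
(`normalize_screen`, `rank_sirnas`, `score_genes`, `call_validation_hits`,
…) and run on any long-format well TSV, not only simulated ones.

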