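# Methods notes

Assumptions, parameter defaults and numerical choices for each module, and
what the synthetic generator does and does not emulate. No number in this
document is an empirical claim beyond what the test suite and
`scripts/acceptance.py` actually compute.

## Expression containers and preprocessing (`expression_io`)

- Matrices are cells × genes, either raw FPKM or log2(FPKM+1); log-scale is
  required by every downstream statistic and double log-transformation is
  refused. The transform is exact on representable values (0→0, 1→1, 7→3).
- `filter_genes` keeps genes detected (value > 0) in **more than**
  `min_cells = 2` cells — an exclusive threshold, matching the convention
  "expressed in at least 3 cells" for the default — and drops zero-variance
  genes, which carry no information for correlation-based analyses and break
  Pearson/Spearman denominators.
- TSV round-trips use `%.17g` formatting so that write→read is bit-exact,
  which is what makes whole-pipeline byte-reproducibility possible.

## Synthetic generator (`synthetic_data`)

The generator's defaults are the simulated study conditions; they were fixed
once, during design, to realize the recovery regime the analyses are
specified against, and are not tuned per test.

- **Lineage**: each cell has a latent position u ~ U(0,1); true type is AP
  (u < 1/3), BP, or N (u > 2/3). Programs are log2-additive on a N(4,1)
  background with effect size 2.0 (≈4-fold):
  - NSPC genes decline as max(0, 1 − u/off) with per-gene off ~ U(0.5, 1);
  - neuron genes rise as max(0, (u − on)/(1 − on)) with on ~ U(0, 0.5);
  - BP genes are tents around u = 0.5 with half-width ~ U(1/6, 1/3).

  The per-gene geometry matters: if all genes shared one ramp, the terminal
  trajectory segments would differ only in scale, which Pearson correlation
  cannot resolve, and no correlation-based pseudotime could order them.
- **Cycle**: G2M-phase progenitors add a per-gene-weighted (U(0.2, 1.8))
  cycling program on low, varied baselines; neurons are always G1.
- **Species**: a small gene set (4 % of genes) carries a progenitor-biased
  ramp plus a +2.0 log2 shift in human AP cells only.
- **Noise**: Gaussian with sd 0.3 on the log scale. **Dropout defaults to
  0**, modeling deep full-length (Fluidigm/SMART-seq-like) libraries in
  which marker-gene dropout is rare. Magnitude-independent Bernoulli
  dropout zeroes ~6-log2 markers and destroys local correlation structure
  even at 1–2 %, so it is a knob (`dropout_rate`) exercised explicitly in
  tests rather than a default condition.
- Also generated: a zone reference from pseudotime-quartile means; mitotic
  tracks with truncated-normal phase durations snapped to the 1.1-min frame
  grid; orientation tracks with configurable drift and jitter; cumulative
  labeling curves from the closed-form model; and toy two-species alignments
  with configured SNVs and indels.
- Not emulated: library-size variation, batch effects, doublets, branching
  lineages, transcriptional bursting, read-level counts (values are
  log-FPKM-like directly), and sequence evolution beyond point SNVs and
  short indels.

## Signatures (`signatures`)

- PC1 of the reference matrix defines the NSPC↔neuron axis; the top/bottom
  `n_top = 100` genes by correlation with PC1 scores are the signatures.
  PC1's sign is arbitrary, so an optional marker list orients it.
- A cell's signature score is the fraction of its expressed genes
  (log2 value > 5, i.e. FPKM > 31) that belong to the signature; with no
  gene above threshold the score is undefined (NaN), not zero.
- `select_informative_genes` tests each gene's loading correlation against
  `n_perm = 999` permutations and keeps p < 1e-3, at most `max_per_pc = 200`
  genes per component over `n_pcs = 6` components. The p-value is k/n_perm
  (no +1), so under an exchangeable null P(p < 1e-3) is exactly 1/1000 per
  test; because the PCs are fitted on the same data the procedure is mildly
  anti-conservative, which the null-calibration test bounds rather than
  denies.

## Classification (`classify`)

- **Zones**: Spearman correlation against four bulk zone profiles, assigned
  to the argmax; constant cells are `unassigned`; at least 10 shared genes
  are required for a meaningful rank correlation.
- **Types**: Pearson nearest-neighbour against a labelled fetal reference
  over a marker panel; subtype labels (AP1, N2, …) collapse to AP/BP/N.
  Exact ties resolve to the lexicographically first reference cell and are
  logged.
- **Cycle**: hierarchical clustering (correlation distance) on G2M genes,
  cut at three clusters; highest-mean cluster is G2M, lowest G1, middle
  intermediate. **Ward linkage is the default**: with a three-way cut,
  average linkage tends to peel off outlier singletons and leave the two
  real phase blocks merged, while Ward's variance-minimising merges align
  the cut with the phase structure. `linkage_method="average"` restores the
  classical choice.

## Lineage network and pseudotime (`lineage_network`)

- Edges connect cell pairs with Pearson r > τ = 0.4 over the chosen gene
  subset; constant cells are excluded with a warning.
- Pseudotime: complete graph with weight 1 − r, minimum spanning tree
  (Kruskal with deterministic lexicographic tie-breaking), backbone = the
  tree diameter path, and every cell projected to its nearest backbone node.
  All tie-breaks are by sorted cell id, so results are reproducible.

## Differential expression (`diffexpr`)

- Per-gene z = (U − μ ± 0.5)/σ with tie-corrected variance; zero-variance
  genes get z = 0. The normal approximation is validated in-tests against
  exhaustive enumeration of small group assignments.
- Specificity calls threshold the z distributions at mean ± k·SD
  (ddof = 1): k_type = 1 for AP-vs-N, k_species = 2 for human-vs-chimp, and
  a species call additionally requires matching type specificity, so a
  "human-up-AP" gene must be AP-biased and human-up. Degenerate (zero-SD)
  distributions produce no calls and a warning.
- `ap_specificity_score` = mean_AP − max(mean_iPSC, mean_EC); genes missing
  from any source are NaN, not dropped.

## Consensus masking (`consensus_mask`)

- Coordinates are 0-based half-open on the ungapped first (reference)
  sequence. Substituted or N-containing columns mask one base; gap runs are
  masked with ±6 bp flanks (`flank = 6`, matching short-read seed lengths);
  insertions into the other sequence occupy no reference base, so the flank
  extends both ways from the insertion point. Intervals are merged and
  clipped to the sequence.

## Mitosis timing (`mitosis_timing`)

- Five phase durations are successive differences of six event times that
  must sit on the 1.1-min frame grid; prometaphase+metaphase and the total
  are reported as sums.
- Two groups: two-sided Mann-Whitney; three or more: Kruskal-Wallis with
  Dunn's tie-corrected pairwise z tests (unadjusted by default; Bonferroni
  and Holm available). Groups with fewer than three observations are
  excluded with a warning. α = 0.05 throughout.
- Orientation: the maximal plate-angle range between plate formation and
  anaphase onset, and the cleavage angle read at the sample nearest to
  anaphase onset + 2.2 min (two frames), ties to the earlier sample.

## EdU kinetics (`edu_model`)

- Model: LI(t) = min(GF·(t + Ts)/Tc, GF). The plateau is found by scanning
  per-time **mean** labeling indices from the latest time backwards while
  they stay within `plateau_tol = 0.02` of the curve maximum. Judging the
  plateau on means rather than individual replicates keeps replicate
  scatter from spuriously breaking it at realistic noise levels. GF is the
  mean over all plateau observations; the pre-plateau regression uses
  individual replicate points (set `average_replicates=True` to collapse
  them first — both choices are invariant to duplicating observations).
- Ts = intercept/slope, Tc = GF/slope. Fits fail loudly (`FitError`) when
  no plateau exists, fewer than three pre-plateau time points remain, or
  the slope is not positive; the recovery tests count failures as
  infinitely wrong rather than discarding them.

## Pipeline (`pipeline`, `cli`)

- Stages run in fixed dependency order; each reads from and writes to one
  artifact directory, so stages can be re-run individually. The effective
  config is echoed to `config.yaml`, hashed into `manifest.json`, and a
  failing stage leaves a `FAILED` marker naming the stage and error.
- Unknown config keys and stage names are rejected rather than ignored.
- Determinism: a fixed seed makes every artifact byte-identical across
  runs; the simulate stage derives its fetal reference from seed+1 so the
  reference is an independent draw from the same distribution.

## Limitations

- The generator's lineage is a single unbranched continuum; real cortical
  lineages branch and mix cell states.
- Rank-sum z-scores use the normal approximation; for groups far below ten
  cells an exact test would be preferable.
- The PC1 signature assumes the dominant variance axis is the
  differentiation axis; cycling or batch structure stronger than lineage
  would be captured instead.
- The cumulative-labeling fit assumes a homogeneous cycling population with
  a single (Tc, Ts); mixtures bias both parameters.
- The consensus masker handles pairwise alignments only, with no scoring of
  alignment quality.
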