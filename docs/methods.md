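# Methods

## Model and assumptions

The pipeline treats a **regulon** — one transcription factor (TF) plus the
target genes it activates — as the unit of regulatory analysis. The design
assumes (i) stage-labeled bulk expression with at least two replicates per
stage; (ii) that activating regulation shows up as positive monotone
co-expression between a TF and its targets across samples; and (iii) that a
genuine target's promoter is accessible, and carries the TF's binding
motif, in stages where the TF is active. Inference proceeds in two
complementary passes: a deliberately *recall-oriented* co-expression pass
proposes candidate targets, and the chromatin/motif pass supplies the
specificity by discarding TFs without motif enrichment and targets without
a motif-bearing peak. Differential activity across consecutive stage
transitions then identifies candidate master TFs as regulons that flip
direction between de-differentiation and re-differentiation.

### Candidate regulons

Targets are genes with Spearman ρ ≥ `corr_threshold` against the TF over
all samples (average-tie ranks; positive links only, following the
activating-module convention of regulon analysis). With n ≈ 9 samples the
null standard deviation of ρ is ≈ 1/√(n−1) ≈ 0.35, so no cutoff can be both
sensitive and specific on correlation alone; the default
`corr_threshold = 0.3` intentionally favors recall and relies on motif
pruning for specificity. A TF with constant expression is skipped
(correlation undefined), and regulons below `min_size = 5` targets are
dropped.

### Motif support

Peak sequences are fixed-width windows (default 500 bp). PWM scanning
scores every offset on both strands as Σ log₂(p_base/q_base) against a
background (uniform by default); windows containing N are skipped. The hit
threshold defaults to 80 % of the PWM's maximal attainable score, common
PWM practice. A pseudocount (10⁻³ when regularizing raw probability
matrices) avoids −∞ log-odds. Peaks are assigned to the gene with the
nearest transcription-start site within `max_distance = 10 kb` of the peak
midpoint (ties to the lexicographically smaller gene ID, a documented
arbitrary tie-break). Enrichment per TF and stage is the upper-tail
hypergeometric probability of the observed number of hit-bearing peaks
among the peaks assigned to the TF's candidate targets (foreground),
relative to all peaks accessible in that stage (universe). A regulon
survives if enriched (p ≤ `enrichment_alpha = 0.05`) in **at least one**
stage — a deliberate choice, since a stage-specific TF's support can exist
only where it is active.

### Activity

Per sample, genes are ranked by descending expression; ties are broken by a
seeded random permutation so the ranking is strict and the recovery curve
uses exact integer arithmetic (the tie seeds are recorded in the run
manifest). With k = ⌊`top_fraction`·N⌋ and H(i) = number of targets at rank
≤ i, activity = Σᵢ₌₁..k H(i) normalized by its regulon-specific maximum
Σᵢ₌₁..k min(i, m), m = min(|targets|, k), which makes scores comparable
across regulon sizes. Activity is therefore invariant to any strictly
increasing per-sample transform of expression.

`top_fraction` matters. The conventional 5 % window presumes transcriptome-
scale universes (N ≈ 2·10⁴); in a simulated universe of N = 200 genes whose
baselines span two decades, a 2× induction moves a target by roughly
(log₂2 / log₂ dynamic-range) · N ≈ 30 rank positions, so a 10-gene window
rarely sees it, the inactive-stage AUC degenerates to exactly zero, and the
variance gate is forced into a low-power Welch branch with ~2 degrees of
freedom. The pipeline default for these small universes is
`top_fraction = 0.5` (the library-level default for `score_activity` stays
at the conventional 0.05); the window should be wide relative to where a
plausible induction can move a target.

### Differential statistic and ranking

Per regulon and stage pair (x = stage-A replicates, y = stage-B):

* F gate: F = s²ₓ/s²ᵧ (n−1 denominators), two-sided p = 2·min(CDF, SF)
  capped at 1, df (nₓ−1, nᵧ−1). Variances compatible (p > `alpha_var` =
  0.05) → pooled Student t (df nₓ+nᵧ−2); otherwise Welch t with
  Satterthwaite df. Both groups constant: the row is reported
  non-significant rather than dropped, keeping the FDR family stable.
* Effect size: log₂(mean(y)/mean(x)); a zero mean activity is replaced by
  ε = 10⁻⁶ (logged) since AUCs are nonnegative.
* Benjamini–Hochberg adjustment across the regulons of the comparison;
  direction assigned at `alpha_fdr = 0.05` and `fc_min = 0`.
* The volcano table also carries `dot_size` (mean TF log-expression over
  both stages) raw and centered — both are emitted because either reading
  of "size encodes average regulon expression" is defensible.

Master-TF candidates must be significant in both transitions with opposite
fold-change signs. The default combined score Σ(−log₁₀ FDR × |log₂ FC|) is
symmetric and monotone in both inputs; a rank-product scorer is available
behind `scorer="rank_product"`. The top k = 4 per direction are flagged.

### Grouping, signatures, stage mapping

* `group_regulons`: k-means (k = 4, n_init = 10, seeded) on z-scored
  stage-mean activity profiles; clusters are relabeled deterministically by
  their centroid's value at the progenitor stage, ascending, so G1 is the
  most mature-skewed group and G4 the most progenitor-skewed. In the
  end-to-end pipeline grouping is descriptive and is skipped with a
  manifest warning when fewer than k distinct profiles survive pruning.
* ssGSEA: ES = Σᵢ [P_in(i) − P_out(i)] with P_in the r^τ-weighted in-set
  ECDF of rank scores r_g = N − pos_g + 1 (τ = 0.25) and P_out the
  unweighted out-of-set ECDF; ranks, not raw expression, for determinism
  and transform invariance; ties broken by gene label. The raw running-sum
  ES is reported; optional normalization divides by the global max−min
  score range (the usual cross-sample convention), and is refused for
  single-sample matrices where the range is undefined. Marker signatures
  default to the mean of per-gene z-scores, which is faster and
  sign-interpretable; regulon–signature correlations are computed for both
  activity and TF expression, since either can be read as the "level" being
  correlated.
* Stage mapping: Pearson correlation on log₂(x+1) profiles over the common
  expressed genes (nonzero in ≥ 1 column of each dataset — no expression
  floor is imposed, a documented choice), between each sample and each
  column of a reference developmental panel.

## Synthetic data

The generator emulates a 3-stage organoid trajectory (mature → progenitor →
re-differentiated; labels SHO/HHO/HBO) with `reps_per_stage = 3` bulk
replicates. Expression of target g of TF t in sample s is
baseline_g · effect_size^activity(t, stage(s)) · exp(ε), ε ~ N(0,
noise_sd); the TF's own expression follows the same law. Defaults: 200
genes, 10 TFs × 15 targets, effect_size 2, noise_sd 0.2 (natural-log
scale), baselines log-uniform over 10–1000. Multiplicative log-normal noise
keeps values positive and rank structure interpretable. The default
activity design plants two progenitor-up TFs (active only at the middle
stage), two mature-up TFs (active only at the flanking stages), and six
constitutively active TFs that provide regulons with no differential
signal. Replicate count, noise level and baseline range are generator
choices of what a small bulk organoid series realistically looks like, not
values taken from any particular dataset.

Each target promoter receives one 500-bp peak centered on its TSS (toy
genome: one gene per 25 kb on chr1), emitted in a stage's accessible set
iff its TF is active there, with one motif instance sampled base-by-base
from the TF's PWM at a uniform-random offset. Instances are
rejection-sampled until they clear the scanner's own 80 %-of-max threshold
(falling back to the consensus), so the planted-support invariant — every
accessible planted peak contains a detectable hit — holds by construction.
Background peaks (default 40) carry random sequence on a separate contig
and are accessible in every stage. Motifs are 8-mers with one dominant base
(probability 0.9) per position.

Marker gene sets are emitted from the planted programs: the hepatocyte
signature is the target set of the first mature-up TF, the cholangiocyte
signature that of the first progenitor-up TF, and the stemness set the
union of progenitor-up target sets — making the expected signs of the
signature correlations part of the ground truth. The reference panel
interpolates, in log space, between the progenitor-stage and mature-stage
mean profiles over `n_ref_stages = 9` columns, so correlation-based stage
mapping has a known optimum at each end of the gradient.

**What the simulation does not capture.** Real bulk data have library-size
and batch effects, correlated gene–gene noise, TF–TF hierarchies, indirect
targets, motif databases with cross-TF similarity, and peaks whose
accessibility is graded rather than binary. Passing the planted-recovery
and calibration tests therefore demonstrates the internal consistency and
statistical behavior of the method under its own assumptions, not its
accuracy on real organoid data.

## Numerical and design choices

* Spearman via average-tie ranks + Pearson; at zero noise a TF and its
  targets are exact monotone copies and ρ = 1 despite within-stage ties.
* All coordinates are 0-based half-open (BED convention); hit strands are
  reported but unused downstream.
* PWM probability rows are renormalized only when they deviate from 1 by
  more than 10⁻¹², so already-normalized matrices (and file round-trips)
  pass through bit-identically; MEME minimal files are written at 17
  significant digits and TSVs are read with round-trip float parsing for
  the same reason.
* Zero-variance cases are made explicit: both groups constant → gate
  passes, t = 0, p = 1; exactly one group constant → Welch branch.
* The end-to-end analysis requires ≥ 3 stages (two transitions) for
  ranking; with exactly two stages the differential tables are still
  produced.
* Problem sizes in the test suite and acceptance script (50 recovery
  simulations, 300 null simulations, 200-gene universes) are chosen so the
  statistical claims are testable at desk scale with tight seeds.

## Known limitations

* Co-expression is correlation-based and undirected; TF→target causality is
  assumed, not inferred, and TF–TF regulation is out of scope.
* The hypergeometric enrichment tests presence/absence over whole windows;
  positional (central) enrichment within peaks is not modeled.
* The activity statistic is rank-based and shares AUCell's insensitivity to
  inductions that do not change rank order within the scoring window.
* With 3 replicates per stage the Welch branch has very low power; the
  F gate is kept at α = 0.05 regardless, and borderline regulons can be
  missed in any single simulated series (the recovery guarantee is a
  95 %-of-seeds statement, not per-seed).
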