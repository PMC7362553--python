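# Methods

## Model and pipeline

`boostgrn` treats GRN inference as *p* independent supervised regression
problems, one per target gene, in the tradition of ensemble feature-
selection methods for network reconstruction. For target *j* with
candidate regulators *i ≠ j*:

1. **Lagged features.** Each sample pairs the target's expression at time
   *t* (response) with, per regulator, the decayed accumulation
   `Σ_{m=1..k} x_i(t−m) δ^(m−1)` of that regulator's expression over the
   *k* previous time points. The most recent lag has weight 1 (δ⁰);
   earlier lags decay geometrically. Lags never cross replicate-series
   boundaries, and the first *k* points of each series are used only as
   context, so a series with *T* points contributes *T − k* samples.
   Time stamps are treated as ordinal steps; uneven spacing does not
   rescale δ.
2. **Boosted regression.** An ensemble of depth-limited regression trees
   is fitted by gradient boosting (squared-error loss; with the ½(y−ŷ)²
   convention the per-sample hessian is 1, so `min_child_weight` acts as
   a minimum child sample count). Edge confidence is the regulator's
   split count: the number of internal nodes over all trees that test
   that regulator. Split counts — not gain or cover — are the contract;
   they are cheap, scale-free, and robust to the tiny learning rates used
   here.
3. **L2 normalization.** Per-target confidence vectors are divided by
   their Euclidean norm so independently fitted subproblems are
   comparable in one global ranking. All-zero columns (a target nothing
   ever split on) remain zero rather than dividing by zero.
4. **Knockout prior (optional).** `I_ij = |xᴷᴼ_ij − mean_j| / sd_j`, the
   absolute z-score of gene *j*'s expression under the knockout of *i*
   within *j*'s column across all knockout experiments, multiplies the
   normalized confidence. Regulators lacking a knockout row, and genes
   whose knockout column has zero spread, get the neutral factor 1.
5. **Regulator-variance reweighting.** Each regulator row is multiplied
   by the population variance of its own weights over targets *j ≠ i*.
   Sparse networks concentrate a true regulator's weight on few targets,
   giving high variance; a flat (uninformative) profile is damped, a
   constant row is exactly zeroed.
6. **Ranking.** All ordered pairs, self-pairs excluded, sorted by score
   descending with (regulator, target) lexicographic tie-breaking —
   a deterministic total order.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 2 | previous time points accumulated per regressor |
| δ | 0.45 | geometric decay of older lags, in [0, 1] |
| n_trees | 1000 | boosting rounds |
| max_depth | 4 | maximum tree depth |
| min_child_weight | 4 | minimum samples per child (hessian = 1) |
| subsample | 0.7 | row fraction per tree |
| colsample_bytree | 0.9 | feature fraction per tree |
| eta | 0.0008 | learning rate |
| γ | 0 | per-leaf split penalty |
| λ | 1 | leaf-weight L2 penalty |

k, δ and the boosting settings follow the published tuning for
DREAM4-scale data; γ and λ keep the backend's conventional defaults
since no tuned values are reported for them. `sd_mode` defaults to the
sample (n−1) standard deviation — the safer small-n choice, "standard
deviation" being otherwise ambiguous — with a population option. The
gene's own knockout row is included in its column statistics by default
(the prior is defined over *all* knockout experiments);
`--exclude-self-knockout` is available because a self-knockout forces
expression toward zero and can inflate the spread.

## Order of operations and open choices

Normalization precedes prior fusion, which precedes the variance
reweighting; the variance is computed on the weights as they stand
entering that step (post-fusion when the prior is on). The variance
reweighting is applied in both the prior and no-prior pipelines by
default — its hubness rationale does not depend on knockout data — and
can be disabled with `--no-variance-update`. Per-target boosting seeds
are derived from the single pipeline seed via independent seed
sequences, so results are identical whatever order targets are
processed in.

## Numerical choices

* Tree training runs single-threaded with the exact greedy split finder;
  a fixed (data, config, seed) triple reproduces bitwise-identical
  importances and byte-identical output files.
* A constant response admits no gain-positive split: the fit is skipped
  and all counts are zero.
* Base prediction is the response mean.
* Constant regulator rows in the variance step are zeroed exactly
  (no floating-point residue).
* Edge scores are written with 12 significant digits; expression and
  knockout tables with 17 (lossless for doubles).
* AUROC uses the rank (Mann–Whitney) formulation with midrank ties;
  AUPR sums precision over recall steps without interpolation. Universe
  pairs absent from a ranking are scored strictly below every ranked
  pair, tied together.

## Synthetic benchmark

The generator emulates the *shape* of the DREAM-style in-silico
benchmarks so the pipeline can be exercised end-to-end with a known gold
standard. Defaults: 20 genes, 40 directed edges, 5 replicate series of
21 time points, observation noise sd 0.1, interaction strengths uniform
in [0.5, 1.0]; a 100-gene/10-series configuration mirrors the challenge
size exactly.

Design choices, made once on first principles:

* **Topology.** Sparse graphs draw edge sources with Zipf weights, so a
  few hub regulators hold most edges — the heavy-tailed out-degree of
  real transcriptional networks, and the regime the variance
  reweighting is designed for. Dense requests fall back to uniform
  sampling.
* **Dynamics.** `x_j(t) = f(b_j + Σ_i s_ij x_i(t−1)) + ε`, clipped at 0,
  with basal drive b_j ~ U(0.05, 0.25) and ε ~ N(0, noise_sd). The
  basal term plays the role of basal transcription: without it the
  noise-free system collapses to the all-zero fixed point and knockouts
  become uninformative.
* **Transfer function.** A unit-slope-at-origin Hill saturation
  `f(u) = c·u/(c + u)` with ceiling c = 8 (a pure linear mode exists for
  analytic checks). Unit initial slope means the interaction strengths
  are the true small-signal gains of their edges; with a much lower
  ceiling the saturation squashes multi-parent inputs and the stated
  observation noise drowns the regulatory signal entirely (even an
  oracle ranking by lagged correlation degrades toward chance), while a
  near-linear unbounded transfer lets strong cycles diverge.
* **Knockouts.** Steady states are approximated by 50 iterations of the
  noise-free map from the mean observed state with the knocked-out gene
  pinned at zero — mirroring the steady-state character of the
  challenge's knockout measurements.
* **Edge signs.** All-positive by default; a signed mode flips each
  strength with probability 0.3.

What the generator does **not** emulate: kinetic (ODE/SDE) transcription-
translation models, measurement-protocol perturbations, mRNA-vs-protein
distinction, signed repression by default, or missing data. Passing the
recovery tests therefore shows the pipeline extracts lagged causal
structure from noisy saturating dynamics at realistic shapes — not that
it attains any particular accuracy on laboratory data.

## Problem sizes in the test suite

The recovery study runs ten 20-gene benchmarks with boosting reduced to
200 trees at learning rate 0.05 (the 1000-tree/0.0008 defaults are sized
for 100-gene challenge data; at 20 genes the reduced setting reaches the
same ranking quality in a fraction of the time). The determinism check
runs the 100-gene, 10-series shape with 100 trees. `scripts/acceptance.py`
uses the same sizes.

## Known limitations

* Split-count importance is noisier than gain-based importance for weak
  signals; it is kept as the method's defining contract.
* Monotone-transform invariance of the trees holds exactly for the
  deterministic builder; with row subsampling enabled the backend's
  random stream interacts with feature values, so two datasets differing
  by a monotone warp may sample different rows.
* Every knockout experiment is assumed present or absent as a whole row;
  there is no imputation for partially observed knockouts.
* Self-regulation is excluded by construction and never scored.
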