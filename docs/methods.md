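# Methods

This note documents the statistical procedure the package implements, the
choices made where the design was open, and what the synthetic benchmark
does and does not establish.

## The procedure

The pipeline hypothesises regulatory interactions around a binary driver
phenotype (e.g. low/high expression of an oncogenic driver in a tumour
cohort) from a probes × samples expression matrix, in four tiers:

1. **Phenotype dichotomisation.** When labels are not supplied directly,
   samples are classed 1 iff a designated driver probe's value strictly
   exceeds its median across samples. How the driver should be
   dichotomised in a real cohort is a scientific choice the package does
   not make for the user; the median split is the default because it
   guarantees two populated classes on continuous data. The driver probe
   is always an explicit parameter — the package never guesses which
   probe (or composite score) represents the driver.

2. **Single-probe screening.** Each probe is scored by a one-input
   multi-layer perceptron (MLP) trained to predict the phenotype from
   that probe alone, under Monte Carlo cross-validation: for each of
   `n_resamples` (default 10) resamples the samples are randomly split
   60% / 20% / 20% into training, test and validation subsets; the score
   is the mean validation-subset MSE. The test subset steers early
   stopping only; ranking uses the validation subset, which is blind to
   training, to avoid the optimism of the early-stopping monitor.
   "Screening" here is strictly the univariate ranking stage — no forward
   stepwise panel growth is performed, since the downstream inference
   consumes a fixed top-k panel. The top 100 probes (configurable) form
   the marker panel.

3. **Interaction inference.** For each marker `t` in the panel, an MLP is
   trained to predict the min-max-scaled expression of `t` from all the
   other markers, again over Monte Carlo resamples (train/test splits;
   the validation fifth is left unused here). Each trained model is
   collapsed into per-input influence scores, averaged over resamples to
   fill column `t` of the directed marker × marker interaction matrix.
   The diagonal is structurally zero. Both directions of a pair are
   estimated independently and never symmetrised.

4. **Network analysis.** The matrix is filtered to the top-k directed
   edges by |influence| (default 100), hubs are ranked by *weighted*
   degree — the sum of |influence| over incident retained edges,
   incoming plus outgoing — and the network is exported as a Cytoscape
   SIF file (`activates`/`represses` by sign) plus node/edge attribute
   tables.

## The influence score

The default score for input `i` of a trained network is the
connection-weight product

    influence(i) = Σ_h W1[i, h] · W2[h]      (bias weights excluded),

the standard weight-based variable-importance measure for one-hidden-layer
perceptrons. It is a pure function of the trained weights, signed —
positive values are read as putative activation, negative as repression —
and cheap enough to evaluate for thousands of models. Because both layers
are sigmoidal, the product of the path weights is a first-order proxy for
the partial effect of input `i` near the operating point; it is not a
causal effect estimate. A sensitivity alternative (move input `i` from 0
to 1 with the other inputs held at their training means; record the output
change) is available as `method="sensitivity"` for comparison; it probes
the fitted function far from the data and is not the default.

## The network

A three-layer perceptron: inputs, `H = 2` logistic-sigmoid hidden units,
one logistic-sigmoid output. The tiny hidden layer and the small initial
weights (`Normal(0, 0.1²)`) deliberately constrain capacity against
overfitting wide expression data. Training is online backpropagation on
the squared error with learning rate 0.1 and momentum 0.5, the classical
parameterisation for this architecture; per-sample updates (with fresh
per-epoch shuffling) rather than batch updates, because the momentum
defaults assume the online regime. Squared error is used for both the 0/1
classification targets of screening and the [0,1]-scaled regression
targets of inference, which makes the two stages share one training path.

Early stopping: after each epoch the MSE on the held-out test subset is
recorded; training stops when it has not improved for `patience = 20`
epochs or at `max_epochs = 300`, and the weight snapshot from the best
test-MSE epoch is returned. The stopping rule is configuration, not
doctrine — both knobs are exposed and recorded in provenance headers.
Targets must lie in [0, 1] (the output unit's range), which is why
expression targets are min-max scaled per probe before inference.

## Randomness and reproducibility

Every stochastic step draws from `numpy` generators seeded through
`SeedSequence` derivations of a single master seed:

* per-probe screening seeds mix the master seed with a CRC32 of the probe
  ID, so scores are invariant under row reordering;
* per-(target, resample) inference seeds mix the master seed, target
  index and resample index, so any single target can be recomputed alone;
* pipeline stage seeds mix the master seed with a hash of the stage name,
  so adding a stage never perturbs earlier stages.

Two runs under one master seed produce byte-identical stage artifacts
(the manifest's wall-clock timings excepted); this is asserted in the
test suite.

## The synthetic benchmark

`anninfer.synthetic` generates cohorts from a linear-Gaussian model: a
Bernoulli(0.5) class per sample, an additive driver effect (default 2.0,
against noise SD 0.5 — a strong, microarray-plausible log-intensity
separation) on a chosen subset of probes, and planted directed edges
(|beta| in [1, 2], random sign) applied in one in-index-order propagation
sweep, so each edge adds `beta · x_source` to `x_target` and cycles
simply truncate after one pass. Edges are planted among driver-associated
probes so that a correct screen retains their endpoints. These defaults
are the package's reference study condition: recovery is near-certain at
a few hundred samples, which keeps the whole benchmark suite inside a few
minutes on one core (the bundled checks use 10–50 probes, 10–15 marker
panels and 200–300 samples).

What the generator does **not** emulate: probe-level microarray artefacts
(batch effects, saturation, cross-hybridisation), heavy-tailed or
heteroscedastic noise, unbalanced cohorts (prevalence is configurable but
the benchmark uses 0.5), and nonlinear or time-resolved regulation.
Passing the benchmark therefore shows the machinery is correct and can
recover linear-Gaussian structure at realistic effect sizes; it does not
certify recovery rates on real cohorts.

## Numerical choices and degenerate inputs

* Score ties in ranking, and |influence| ties in edge filtering, are
  broken lexicographically by probe/marker ID, so all orderings are
  total and deterministic.
* Probe rows are min-max scaled over **all** samples (one affine map per
  probe), not per split: the transform is monotone, so the per-split
  leakage is a scale factor only; fitting it per resample would make
  probe scores depend on split draws through the scaling as well.
* A constant probe row cannot be scaled and raises an error naming the
  probe; an all-identical driver row makes the median split degenerate
  and raises rather than emitting a one-class phenotype.
* A training split that contains only one class is redrawn (up to 100
  attempts) with a derived seed before erroring.
* A resample whose training produces non-finite weights is skipped with
  a warning; a target whose resamples all fail aborts inference naming
  the target. Under default hyperparameters on scaled inputs this path
  is not exercised (property-tested).
* Early-stopping improvement is strict (`<`); on a plateau the earliest
  best epoch wins, again for determinism.

## Known limitations

* Influence scores have no inferential calibration: resample SDs are
  reported as a stability diagnostic, but no null distribution or FDR is
  attached to an edge. Filtering "the top 100" is a presentation rule,
  not a significance statement.
* "Top 100 interaction values" is interpreted as the top 100 *directed*
  edges by absolute influence; an undirected collapse is a trivial
  post-processing step users can apply, but is not built in.
* With strongly collinear markers (e.g. many probes tracking the same
  latent driver), weight-based credit can spread across correlated
  inputs; the multivariate fit mitigates but does not eliminate this.
* The screening stage is univariate by design and will miss probes whose
  association with the phenotype is purely conditional.
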