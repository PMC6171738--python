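# Methods

## The population model

A cell cluster of `N` neurons (default 360, the local-interneuron total of
the *Manduca sexta* lateral cell cluster) is modelled as a boolean matrix
with one column per transmitter.  One realization draws, for each
transmitter, an integer count from `Normal(mean, sd)` — rounded half-up and
clipped to `[0, N]` — and marks that many uniformly chosen cells positive,
independently across transmitters.  Nothing else is structured: there is no
spatial information, no per-cell covariate, and no left/right or
per-specimen distinction inside a single realization (replicate structure
lives in the synthetic-data generator).

Counts are integers because cells are; the rounding and clipping conventions
are the package's own choice (half-up, so a mean of 12.5 gives 13) since
count distributions near the bounds are not otherwise specified.  The
population size itself may be drawn (`Normal(population_mean,
population_sd)`, floored at 1); by default its SD is 0.

Directed coexpression ratios `ratio(X->Y) = |X+ & Y+| / |X+|` are computed
per realization.  A Monte Carlo run (default 10,000 iterations) records the
per-pair mean and SD across iterations.  Pairs whose source set is empty in
an iteration are skipped for that pair in that iteration (counted in
`n_defined`) rather than treated as 0, because the ratio is undefined, not
zero.  Under independence with fixed counts the overlap is
`Hypergeometric(N, n_X, n_Y)`; this closed form is the main correctness
oracle for the simulator.

Randomness: one top-level seed; iteration `i` uses the stream
`SeedSequence([seed, i])`, so results are bit-reproducible and independent
of how iterations might be chunked.

## Rule semantics

A rule (X -> Y, p) clamps a directed probability: exactly `round(p * n_X)`
X-positive cells are forced Y-positive, and Y's residual quota
(`n_Y - forced`, floored at 0) is assigned uniformly among cells that are
neither X-positive nor already Y-positive.  Assigning the residual to all
cells instead would push the realized ratio above `p`; restricting it to
non-source cells makes the clamp exact up to rounding granularity
(`|ratio - p| <= 0.5 / n_X`).

Rules are monotone (set-only): a later rule never removes a membership.
When several rules share a target the forced sets are built rule by rule
(zero-probability rules act first as exclusion zones) and the residual is
filled once per target, outside every source.  Interacting rules can push a
realized ratio off its clamp; such conflicts are reported in the
realization log, never silently corrected.  If a forced set exceeds the
drawn target count, the count is inflated for that iteration and logged; if
the residual quota exceeds the available pool it is capped and logged.

The "GABA constraint" of the constrained models is expressed as a
population-size restriction (`population_mean = 170`, the GABAergic LN
total, SD configurable and 0 by default) rather than as a rule, since it
asserts that the peptidergic action happens inside the GABAergic
subpopulation.

Model enumeration produces every rule subset of a pool up to a maximum
size, ordered by size then lexicographically, with the empty subset as the
independent model.  The default pool is the observed-ratio table itself,
excluding the FMRF/MIP pair (not reliably measurable in the source data)
and all AST-A peptide pairs (never reported).

## SDI statistics

For one directed pair, `SDI = |mean_model - mean_observed| /
max(sd_model, sd_observed)`.  Three choices deserve note:

- **Absolute difference.**  The interpretation scale (0 perfect, 1 within
  one SD, 2 not replicated) and the summation across pairs only make sense
  for magnitudes; signed values could cancel in the weighted sum.
- **Weights use observed overlaps.**  `weighted SDI = sum SDI *
  (n_coexpressed / n_total)` with `n_coexpressed` the *observed*
  coexpressing-cell count, so the weights are identical for every model
  being compared, and `n_total` fixed at 360 even for population-constrained
  models, so their scores stay comparable.
- **Pairs without an observed SD are excluded** from the weighted sum and
  listed on the report; per-replicate SDs for the packaged ratios were
  never published, so any SDI against the published data needs SDs from
  synthetic replicates or from user-supplied data.

Ranking sorts ascending by weighted SDI, ties broken toward fewer rules,
then label.  Percent improvement is computed against the independent model.

The default pair set for scoring models against the packaged data consists
of the printed directed ratios plus the overlap-identity reverses of the
peptide-peptide ones (`ratio(X->Y) n_X = ratio(Y->X) n_Y`).  GABA enters
only as a target: its own cell total was estimated rather than counted per
staining run, so GABA-sourced ratios are not treated as data.

## The reconstructed fixture

No per-cell data are published, so the package reconstructs one: a pooled
boolean matrix (default 12 replicates x 360 cells, i.e. both antennal
lobes of six brains) whose recomputed directed ratios equal every printed
percentage exactly at one-decimal rounding.  Percentages like 84.6% are
unrealizable with ~12 cells, which is why the pooled scale is the default;
the printed ratios were themselves computed from pooled counts.

Construction is deterministic (no RNG).  For each constrained transmitter a
brute-force search picks the pooled count `n` inside
`replicates * (mean +/- sd)` and integer overlaps `k` such that
`round1(100 k / n)` matches every printed percentage, minimizing the total
absolute deviation (ties to the smaller `n`); if no count works the window
widens once to +/- 2 SD, then the builder fails naming the infeasible pair.
Membership placement is greedy on the cell axis, in a fixed documented
order: the hub peptide (MIP) first with the fully nested peptide (TK) at
its start, the second peptide (Mas-AT) overlapping the hub tail by exactly
the constrained overlap while avoiding TK, GABA as segments sized to each
peptide's GABA overlap with maximal reuse of shared cells, FMRF split
across the Mas-AT overlap / a GABA-positive hub segment / a free tail, and
unconstrained peptides (AST-A) on GABA-positive Mas-AT cells plus a free
tail.  After placement every printed percentage is re-verified from the raw
matrix.

One genuine tension surfaces here: the printed percentages jointly force

```
|GABA| >= |GABA & MIP| + |GABA & Mas-AT| - |MIP & Mas-AT|
```

which at the default scale is 204.75 GABA-positive cells per antennal lobe
— above the ~170 GABAergic LN estimate.  The counts entering different
percentages come from different staining runs, so no single cell population
can satisfy all of them *and* the 170 estimate.  The fixture uses the
minimal consistent GABA total and records it in its manifest; it is a
consistent witness to the printed summary statistics, not a claim about the
actual cells.  Three-way structure beyond the printed pairwise constraints
(e.g. whether the TK/MIP cells are the same cells as the MIP/Mas-AT
overlap) is unconstrained; the fixed placement order makes one reproducible
choice.

## Synthetic data and the recovery experiment

The generator emulates the study design: `n_replicates` (default 12)
independent realizations with counts drawn per replicate at the panel SDs
(interpreted as across-specimen variability), planted rules applied with
the production rule semantics, and a summary of per-pair ratio means/SDs,
mean overlaps and count statistics — exactly what the SDI machinery
consumes as "observed" data.  An optional two-group mode shifts one
transmitter's mean between the replicate halves (emulating the observed
sex difference in Mas-AT counts, means 133 vs 180); it is off by default.
What the generator does **not** emulate: staining efficiency differences
between runs, miscounting, spatial structure, or any correlation beyond
the planted rules.  Passing recovery tests therefore show that the
*pipeline logic* detects dependencies of the planted kind at realistic
noise, not that it is robust to measurement artefacts.

The recovery experiment exploits the fact that model predictions do not
depend on the observed data: each candidate model is simulated once and
ranked against many generated datasets.  It reports the fraction of
datasets in which a model containing the planted rule outranks the
independent model, and in which the independent model's weighted SDI
exceeds 1.

Detection power depends on the distance between the planted probability and
the independence expectation `n_Y / N`.  The canonical planted dependency
(MIP -> Mas-AT at 0.42) is evaluated in the GABA-constrained population
(N = 170), where independence predicts ~0.85 for that pair — the setting in
which the rule was identified.  In the full population (N = 360) the
independence expectation is ~0.40, so a planted 0.42 sits essentially at
the indistinguishability limit and neither model should win consistently;
the test suite checks both regimes.

## qPCR relative expression

`delta-Ct = Cq(receptor) - Cq(RpS3)` per sample, averaged over detectable
samples per tissue; `relative expression = 2^-mean(delta-Ct)`.  Nondetect
conventions: Cq 0 means no amplification; a Cq at or above the threshold
(37 cycles) is nondetectable; `x` means not assayed.  The direction of the
threshold is fixed by the packaged data's own nondetect calls (the TK
receptor is ND in the lateral cell cluster, whose Cqs are 39, 0 and 37.59).
ND samples are excluded from the tissue average and a tissue is ND only
when all of its samples are ND; whether a single ND sample should instead
veto the tissue is not specified by the protocol, so the exclude-then-veto
behaviour is the default and the threshold and grouping are configurable.
Delta-Ct is computed per sample and then averaged, not on averaged Cqs.
The Mas-AT receptor was assayed at a 52 degC annealing temperature, so its
reference is the matching 52 degC RpS3 run; the noisy cells of that run's
RT-minus row (no sharp amplification peaks) are recorded as 0 on load.
Efficiency-corrected models and delta-delta-Ct between conditions are out
of scope.

## Problem sizes and tolerances

Simulations default to 10,000 iterations (Monte Carlo SE of a mean ratio
~0.0005-0.001); the acceptance-grade checks in the test suite use 10,000
iterations, 100 synthetic datasets for recovery and 50 for null
calibration, and compare Monte Carlo means to closed forms within 4
standard errors.  The chi-squared goodness-of-fit check of the overlap
distribution runs at N = 20 with fixed counts and alpha = 0.01, merging
bins with expected counts below 5.  Exhaustive-enumeration oracles run at
N = 8.  The fixture build is exact and takes milliseconds.

## Known limitations

- The rule engine guarantees exact clamps only for non-interacting rules;
  chained or shared-target rule sets are applied deterministically but can
  deviate from their clamps, with every deviation logged.
- The enumeration reproduces the *procedure* of scanning rule combinations,
  not any particular historical list of model runs (the composition of
  such lists is not published).
- Absolute weighted-SDI values against the packaged data depend on the
  replicate SDs, which must be synthesized (the observed per-brain SDs were
  never published); orderings and improvements are the meaningful outputs.
- The fixture is one of many per-cell matrices consistent with the printed
  summaries; only quantities that are functions of the constrained pairwise
  overlaps are meaningful on it.
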