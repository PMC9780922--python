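# Methods

## Model and procedure

The analysis treats a longitudinal culture study as a complete
participant × phase × replicate × group table of concentrations (CFU/ml)
with a per-group detection limit.  The first phase is a run-in reference;
later phases add a dietary component.  The pipeline is:

1. **Prevalence filter.** A bacterial group enters the composition only if
   the proportion of its observations *strictly above* the detection limit,
   pooled over all participants, phases and replicates, strictly exceeds
   0.75.  Both comparisons are strict: a group at exactly 75% is excluded,
   and (a corollary) a threshold of exactly 1 excludes everything.  Pooling
   over the whole table is the least-structured reading of "percentage of
   values"; per-study alternatives can be had by filtering subsets before
   calling the pipeline.
2. **Detection-limit imputation.** Censored observations (below the limit)
   are replaced by the limit itself.  This single-value substitution is
   deliberately simple — it is the study rule, not a censored-likelihood
   estimate — and is idempotent.  Because imputed values sit *at* the limit,
   the strict filter gives identical results before or after imputation.
3. **log10 transform and replicate averaging.** Replicates are averaged on
   the log10 scale (a geometric mean of CFU), matching approximately
   log-normal measurement noise.  `replicate_average="raw"` switches to the
   arithmetic mean of CFU followed by log10.  Detection limits must exceed
   1 CFU/ml so every log10 abundance is strictly positive.
4. **Fractions.** f_ipb is group *b*'s share of the participant × phase
   total.  The default computes shares of the *log10* abundances
   (`fraction_scale="log10"`); `"raw"` computes shares of the
   back-transformed concentrations.  Whether the original analyses took
   fractions before or after the log transform is not decidable from the
   method description alone; both are implemented.  Worth noting: raw-scale
   fractions concentrate mass on the dominant groups and produce much larger
   change profiles — and hence τ magnitudes closer to the published table
   (~0.015) — than log-scale fractions do, but no conclusion of the method
   depends on the choice and the log-scale default follows the stated
   ordering (transform, then fraction).
5. **Changes, mean patterns, τ.** Δ_ipb = f_ipb − f_i,ref,b; μ_pb is the
   cohort mean of Δ; τ_ip = (1/B) Σ_b (Δ_ipb − μ_(−i)pb)² with the
   leave-one-out mean μ_(−i)pb (computed exactly via
   μ_(−i) = (I·μ − Δ_i)/(I−1)).  The plug-in variant (full mean) is
   available and is smaller in expectation — the reason the leave-one-out
   form is the default.
6. **Classification.** Percentile cutpoints of τ pool all participant ×
   phase values (default) and use linear interpolation of order statistics
   (h = 1 + (n−1)p).  Typical: τ strictly below the 40% percentile in every
   intervention phase; atypical: strictly above the 60% in every phase;
   otherwise intermediate.  Strict inequalities mean a degenerate (all-tied)
   τ distribution classifies everyone intermediate.  Heat-map bands use the
   20/40/60/80% cutpoints with right-closed intervals (a value equal to a
   cutpoint falls in the lower band) — an arbitrary but fixed convention.
   Per-phase percentiles are available (`pooling="per_phase"`); pooled is
   the default because it is the variant that reproduces the reference
   study's published classification from its printed τ table.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `threshold` | 0.75 | proportion | study prevalence rule, strict |
| `replicate_average` | `log` | — | geometric mean fits log-normal noise |
| `fraction_scale` | `log10` | — | stated transform-then-fraction order |
| `low`, `high` | 0.40, 0.60 | percentile | responder rule |
| `band_probs` | 0.2/0.4/0.6/0.8 | percentile | five-band heat-map scale |
| `leave_one_out` | `True` | — | avoids optimistic bias in τ |

## Synthetic studies

The generator draws log10 concentrations as

    value[i,p,b,r] = baseline[b] + phase_effect[p,b]
                     + deviation_scale[i]·η[i,p,b] + ε[i,p,b,r]

with standard-normal η (participant-specific departure from the cohort
pattern, the planted typicality dial) and replicate noise ε of SD
`replicate_sd`.  Defaults mirror the reference design: 11 participants,
5 phases, 3 replicates, 10 groups, baselines spanning 4–8 log10 CFU/ml,
detection limit 10² CFU/ml, replicate SD 0.15 log10 units — plausible
culture-technique magnitudes chosen once, since no empirical variance
components are published.  The phase-effect matrix is deterministic (zero in
the reference phase) and mixes monotone trends with phase-alternating
shifts, qualitatively matching how some groups rise or fall across all diet
phases while others flip direction.  The emitted table stores the raw drawn
CFU values together with the detection limit; censoring is applied by the
preprocessing imputer, so the study rules are exercised end to end.

Scenarios: `reference` (mixed deviation scales 0.02–0.20, two near-typical
and three strongly deviating participants), `null` (all scales equal — no
planted structure), `extreme` (scales 0.001 / 0.05 / 0.5 with replicate SD
0.05, for recovery tests).  What the generator does **not** emulate: real
taxon ecology (cross-feeding, substrate dynamics), participant-level
compliance drift, within-phase time trends, and correlated deviations
across groups.  Passing recovery tests therefore show that the statistic
detects participant-level departures of the planted kind, not that it
captures any particular biological mechanism.

## Numerical choices and degenerate inputs

- The leave-one-out mean uses the exact algebraic identity rather than I
  separate re-averages; tests verify both agree to 1e-12, and vectorised τ
  matches a naive triple-loop oracle at the same tolerance.
- Fractions sum to 1 and change profiles to 0 by construction; tests enforce
  1e-9.
- Quantiles: linear interpolation of order statistics.  The original
  analysis used a commercial package whose percentile rule is unknown;
  the rule here reproduces the published classification from the printed
  τ values, which is the strongest available check.
- Ties: classification inequalities are strict (ties → intermediate); group
  sort order in figures breaks ties lexicographically; bands are
  right-closed.
- Single-participant cohorts, empty compositions, missing design cells,
  detection limits ≤ 1 CFU/ml and all-excluded group sets raise typed
  errors rather than producing output.
- Summaries report the sample (n−1) SD.  Recomputing the published table's
  summary from its printed 3-decimal values reproduces every printed number
  except two boundary artifacts of input rounding: one phase SD lands one
  unit of the last digit higher, and one participant mean is an exact
  half-unit tie.  Both are documented in the tests.

## Known limitations

- τ is descriptive; no inferential machinery (p-values, multiplicity) is
  attached, by design.
- The percentile rule and the typical/atypical thresholds are conventions;
  with 11 participants the pooled quantiles are coarse and small τ
  perturbations near a cutpoint can move a label (mitigated by requiring
  the condition in *every* phase).
- Rank invariance of labels holds exactly for increasing affine maps of τ;
  for general monotone maps, interpolated quantiles can shift relative to
  transformed values in contrived cases.
- Figures aim at structural fidelity (orderings, bands, overlays), not
  pixel-level reproduction of any particular report.
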