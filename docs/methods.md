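# Methods

## Scope and data model

The package analyzes *endogenous free peptides* — proteolytic fragments
recovered without tryptic digestion (typically a < 10 kDa ultrafiltrate) and
quantified label-free across experimental conditions (e.g. raw meat and
sous-vide cooking at 52/65/80 °C). Input is a peptide quantification table
(sequence, identification confidence, per-condition replicate intensities)
plus the reference protein FASTA. Everything downstream — cleavage events,
specificity matrices, degradation amounts — is derived from these two
inputs; no spectra are touched.

Confidence is stored as a fraction in [0, 1]; tables reporting percentages
are auto-detected (any value > 1) and rescaled with a logged warning. Rows
below the confidence threshold (default 0.95, the conventional DIA peptide
cutoff) are dropped at load time. The filter is applied per peptide record,
which carries a single confidence value; a per-run filter would need
per-run confidences that the table format does not carry. A missing
intensity cell means "not detected in that replicate" and is read as 0
rather than missing-at-random: DIA non-detection is effectively
below-limit, and downstream sums need a defined value.

## Peptide-to-protein mapping

Every occurrence of a peptide in every protein is found (overlaps
included), deterministically ordered. Matching is exact by default;
`IL-equivalent` mode collapses Leu/Ile, which MS cannot distinguish. The
ambiguity code `X` in a parent sequence matches nothing.

Peptides hitting several sites get a multi-mapping policy:

- `split_weight` (default) — weight 1/n per site. Salmonid references are
  full of near-identical paralogs; discarding shared peptides would gut
  the myofibrillar signal, while splitting conserves each peptide's total
  intensity exactly (the conservation identity tested in the suite relies
  on it).
- `discard_ambiguous` — drop multi-mappers; conservative per-protein
  attribution.
- `keep_all_unit` — weight 1 everywhere; diagnostics only, flagged as
  breaking the weight-sum invariant.

Coordinates are 0-based half-open internally; exports state their
convention in the header.

## Terminome reconstruction

A located peptide `[s, e)` in protein *P* (length *L*) implies an N-side
cleavage at bond *s* and a C-side cleavage at bond *e* (bond *c* lies
between residues *c−1* and *c*). An event records the Schechter–Berger
substrate window P2 = P[c−2], P1 = P[c−1], P1′ = P[c], P2′ = P[c+1]. Events
are **not** constructed when

- the cut is a native protein terminus (s = 0 or e = L) — that end was not
  made by a protease;
- the window would run past a protein end (c < 2 or c > L−2) — partial
  windows would bias column counts;
- the window covers an `X`;
- the peptide has zero aggregated intensity in the condition (no evidence
  of that cleavage there);
- optionally, s ∈ {1, 2} (initiator-Met excision ambiguity; off by
  default since no standard rule exists for food-proteolysis data).

Replicate intensities are aggregated by mean (default; the replicates are
technical injections of one sample), with median and sum available.

N- and C-side events are pooled into a single matrix by default — the
conventional single-heatmap-per-condition presentation; `split_termini`
emits separate matrices. Multiple peptides witnessing the same cut are
counted separately (each is independent evidence); `dedupe_cut_sites`
collapses them, summing weights.

### Specificity matrices

Default weighting is `intensity` (event weight = mapping weight × condition
intensity), matching how condition differences are usually phrased
("intensity of Trp at P2′"); `count` weighting is retained as a robustness
check and coincides exactly with intensity weighting when all weights are
equal. Default normalization is `frequency` (column-stochastic);
`enrichment` divides each residue row by the parent proteins' background
composition and raises a hard error if a residue occurs at a subsite but
has zero background frequency. Frequency and enrichment matrices are
invariant to uniform intensity rescaling. An empty event list yields an
all-zero matrix with `n_events = 0` rather than an error.

Condition contrasts are cellwise differences, ranked by |Δ| with
deterministic ties (subsite order P2, P1, P1′, P2′, then residue
alphabetically).

## Degradation quantification

The degraded amount of protein *p* in condition *c* is Σ (weight ×
aggregated intensity) over its mapped peptides — a sum, not a mean, because
more fragment signal is more degradation evidence. Under `split_weight`
the per-condition amounts conserve total mapped intensity to rounding
error. No cross-condition normalization is applied by default (label-free
injections of one sample per condition have no loading-control concept); a
per-condition total-intensity normalization is available for unbalanced
runs.

## The in-silico digestion simulator

The generator emulates the structure of a DIA peptidomics table, not its
full messiness. Each protease model holds four 20-vectors of subsite
preferences (rescaled to max 1) and a base efficiency; the probability of
cutting a bond is

    p(site) = efficiency × Π_{q ∈ {P2,P1,P1′,P2′}} w_q(residue at q),

an independence (PSSM-like) assumption that makes the observed residue
frequencies at realized cut sites an unbiased estimator of the generative
preferences — the property the recovery tests lean on. Bonds without a
full window, or windows containing `X`, are never cut. Each interior bond
is an independent Bernoulli draw, so missed cleavages emerge naturally.
One model per protein realization is drawn from the condition's mixing
proportions (per-site mixing available).

Fragments between consecutive cuts are kept when their length is within
[5, 30] residues and their monoisotopic mass (standard residue masses plus
water) is ≤ 10 kDa, mirroring an ultrafiltration step; the length window
reflects the practically identifiable range of DIA peptidomics. Base
abundances and per-replicate injection noise are log-normal with a common
σ (default 0.5, a mid-range technical+sampling variability); three
replicates by default. True rows get confidence ~ U(0.95, 1); optional
decoy rows — shuffled true sequences verified not to occur in any parent —
get U(0, 0.95) and exercise both the confidence filter and the
unmatched-peptide report. With a fixed seed the emitted table is
byte-identical across runs.

For validation scenarios the canonical "hot" protease prefers Trp at P2′
ten-fold with efficiency 0.9 — sized so that digesting 50 random
300-residue proteins yields upwards of two thousand usable cleavage events
per run — and the non-specific reference protease uses efficiency 0.12,
which puts the mean fragment length (~8 residues) inside the length
window.

What the simulator does **not** emulate: retention-time or fragment-ion
structure, intensity-dependent identification probability, shared-peptide
structure between homologous parents (random proteins are nearly
repeat-free), condition-correlated batch effects. Passing recovery tests
therefore demonstrates correctness of the analysis chain, not robustness
to every artifact of real LC-MS data.

## Texture profile analysis

Two-cycle TPA curves (force in gf vs time in s) are segmented into maximal
above-threshold episodes after subtracting the modal pre-contact force
(rounded to 3 decimals) and clipping at zero. Sub-threshold gaps shorter
than 0.5 s are merged to tolerate noise flicker at the contact toes.
Exactly two episodes are required; single-cycle curves are rejected
because cohesiveness and springiness are undefined for them.

- hardness = peak force of cycle 1;
- cohesiveness = area₂ / area₁ (trapezoidal integration);
- springiness = contact duration₂ / duration₁ — a time ratio, equivalent
  to the distance ratio at constant probe speed; durations use the
  linearly interpolated zero-force crossings at the episode edges, which
  keeps ratios exact for piecewise-linear pulses instead of quantized to
  the sampling step;
- resilience = withdrawal area / compression area within cycle 1, split at
  the episode's force peak.

The curve simulator builds two triangular pulses whose closed-form
parameters equal any requested target (apex placed at fraction
1/(1+resilience) of cycle 1; cycle 2 scaled by cohesiveness and
springiness), samples at 1 kHz with the exact pulse vertices inserted into
the time grid, and adds optional Gaussian noise. Noiseless recovery is
exact to ~10⁻⁹ relative; recovery error grows monotonically with noise.

Group comparisons use Dunnett's many-to-one procedure
(`scipy.stats.dunnett`, seeded multivariate-t evaluation for deterministic
p-values). With a single treatment group the adjusted p-value reduces to
the pooled two-sample t-test, and the all-identical-samples case returns
p = 1 for every comparison rather than an error; zero pooled variance with
unequal means is a hard error.

## Numerical and engineering choices

- Matrix TSV serialization uses 17 significant digits (lossless float64
  round-trip); metadata travels in `#` header lines.
- Frequency-mode heatmaps re-normalize columns before rendering, making
  the image invariant to intensity rescaling.
- All randomness flows through `numpy.random.Generator` objects seeded at
  the entry point; pipeline reruns with the same config overwrite
  byte-identical tables and reports.
- Validation problem sizes (50–500 proteins × 300 residues, 10-seed
  panels, 2000-replicate Dunnett null) are chosen so the full suite and
  the acceptance script each run in well under a minute of simulation per
  scenario on a single core.

## Known limitations

- Cleavage inference treats every non-native peptide terminus as a
  protease cut; in-source fragmentation or exopeptidase trimming would be
  misattributed.
- Specificity matrices describe the *mixture* of active proteases; the
  package deliberately does not attribute signatures to named enzymes.
- Degradation amounts are relative within a condition; absolute
  comparability across conditions assumes comparable injections.
- The P2–P2′ window ignores longer-range subsites (P4/P3′ etc.) that some
  proteases use.
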