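# Methods

## Turnover model

The pulse-chase readout is modeled as first-order decay of pre-existing
(heavy-labeled) protein in a stationary pool. For protein *p*, peptide
*j*, chase time *t* (days) and genotype *g*:

    E[heavy] = A_p · ion_j · E · exp(-k_{p,g} t)
    E[light] = A_p · ion_j · (1 - E · exp(-k_{p,g} t))

where `A_p` is protein abundance, `ion_j` a peptide ionization factor
drawn once and shared across all runs, `E` the heavy fraction reached by
the end of the pulse, and `k_{p,g}` the degradation rate constant
(1/day). Assumptions, in decreasing order of importance:

- **Stationary pool.** Synthesis balances degradation, so total
  (heavy + light) abundance is constant over the chase. This is the
  standard reading for postmitotic neurons: old protein is replaced, not
  diluted by division. It also implies the anchored heavy ratio
  R(t) = exp(-k t) independently of `A_p`, `ion_j` and `E`.
- **Single-rate kinetics.** One exponential per protein; no precursor
  pool, recycling of heavy amino acids, or multi-compartment behavior.
- **Shared ionization factors.** `ion_j` is a fixed property of the
  peptide, which is what makes peptide-level self-normalization
  (heavy(t)/heavy(0) per peptide) cancel instrument response exactly.

## Generator parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `chase_times` | 0, 1, 5, 21 | days after pulse end | the experimental sampling grid (in-vitro days 30/31/35/51) |
| `label_efficiency` | 0.90 | fraction | typical two-week heavy pulse endpoint (~90% labeled) |
| `k_log10_mean` | log10(0.15) | log10(1/day) | median half-life ≈ 4.6 d; see below |
| `k_log10_sd` | 0.45 | decades | heavy-tailed rate spread; see below |
| `frac_slowed`, `rate_factor` | 0.2, 0.5 | — | a minority of proteins degrade at half rate in the mutant |
| `noise_cv` | 0.2 | CV | multiplicative lognormal measurement noise on each area |
| `dropout_midpoint`, `dropout_steepness` | 3·10³, 1.5 | intensity, per decade | logistic missingness vs expected total intensity; ≤ 0 disables |
| `abundance_log10_mean/sd` | 5.0, 0.5 | log10 a.u. | spans ~2 decades of MS1 response |
| `ion_log_sd` | 0.5 | ln units | moderate peptide flyability spread |
| `peptides_per_protein` | (3, 8) | count | uniform; typical identified-peptide depth |

The rate distribution is anchored to two marginal facts about this kind
of culture: roughly half of the heavy signal should be gone by day 5 and
~15% should remain at day 21. Under a lognormal with median 0.15/day and
0.45-decade SD, the population averages are E[exp(-5k)] ≈ 0.45 and
E[exp(-21k)] ≈ 0.14, matching both. The long-lived tail this implies
(half-lives of weeks) is a real feature of neuronal proteomes, and it has
consequences for sensitivity discussed under *Limitations*.

Noise is mean-one lognormal (`exp(σz - σ²/2)`, `σ² = ln(1+CV²)`), drawn
independently for heavy and light areas. Missingness acts on the expected
*total* intensity — detectability tracks total ion current, not the heavy
share — so under the stationary-pool assumption dropout is uniform across
chase times. With `noise_cv = 0` the noise multiplier is exactly 1 and
with `dropout_midpoint ≤ 0` missingness is off; draw order is fixed
regardless, so a config plus seed is bit-reproducible.

The IP generator emits, per genotype × replicate, a bait (VCP) run and an
IgG control run. True interactors get Poisson counts proportional to the
observed bait count (proportionality uniform on (0.05, 0.5)) and leak
into IgG with expected fraction uniform on (0, 0.15); background proteins
share one expected count (uniform on (1, 20)) between both runs — the
signature of nonspecific binding. Exclusive interactors are emitted only
in their genotype's runs. Zero-count rows are omitted: absence from a run
is exactly what the exclusivity rule consumes.

### What the generator does not emulate

Ratio compression from co-eluting peptides, arginine-to-proline
conversion, charge-state splitting, shared peptides across proteins,
batch effects between runs, and any correlation between abundance and
turnover. Tests passing on this generator therefore validate the
*procedures* (filters, rollups, tests, set logic) and estimator behavior
under idealized noise — not robustness to those real-data artifacts.

## Analysis procedures and numerical choices

- **Rollup** is the arithmetic mean of heavy areas over matching peptides,
  singletons included; records with zero heavy area carry no heavy
  quantification and are treated as absent (an absent rollup is a missing
  value, never zero).
- **Profile filters**: anchor required at day 0; each later ratio kept
  only if strictly below 1; proteins with no surviving ratio dropped.
  Ratios exactly 1 are excluded (a tie with the anchor carries no decay
  information and upstream rules treat ≥ 1 as artifact).
- **Persistence** uses the strict inequality mutant > control; exact ties
  count as non-persisting. No multiple-testing correction is applied to
  persistence calls.
- **Paired test** (protein-level normalized intensities) is the classical
  paired t; **unpaired tests** (peptide-level values; interactome
  enrichment) default to Welch's form, with the pooled-variance option
  available (`equal_var=True`) for tools that default to it. Degenerate
  inputs short-circuit: identical zero-variance samples give p = 1,
  separated zero-variance samples give p = 0 rather than NaN.
- **Decay fit** is the through-origin least-squares slope of ln R on t:
  closed-form, exact on noiseless input, no initialization or tolerance
  knobs. RSS is reported on the log scale.
- **Interactome rules**: IgG "co-precipitation" means count > `igg_floor`
  (default 0) in the paired IgG run; the > 3 ratio uses raw counts within
  the run pair (both runs share scale; the IgG run has no bait row, so a
  bait-normalized variant of this particular ratio is not definable);
  bait-normalized ratios are used for cross-genotype enrichment; the
  replicate-concordance default requires every replicate, `n_required`
  relaxes it. Proteins absent from a run count as 0 for presence logic
  but contribute no value to ratio averaging. Benjamini–Hochberg is off
  by default (per-comparison α = 0.05) and available as `bh_correct`.
- **Cross-run normalization** is deliberately not applied: anchored
  ratios are invariant to per-run scale factors only if all runs share
  them, but the procedures here never compare raw areas across runs
  except through the anchor ratio, which each genotype computes within
  its own run series.
- **Writers** sort rows by all columns and emit LF/UTF-8 TSV; manifests
  carry SHA-256 digests and no timestamps, making rerun comparisons
  byte-exact.

## Problem sizes

Simulation-based tests use 200–500 proteins with 3–10 peptides each and
50-seed batteries for calibration checks; these sizes give binomial and
Monte-Carlo error bars comfortably tighter than the asserted bands. The
demo config uses 120 proteins.

## Limitations

- With rates anchored to the decay marginals above, a slowed protein from
  the long-lived tail shows a day-1 mutant/control ratio difference under
  2% — below CV-0.1 measurement noise — and slow decayers are also the
  ones the ratio ≥ 1 filter removes from the day-1 common set. All-time-
  points persistence is therefore a conservative, low-recall call at
  realistic noise (recall ~0.7 at CV 0.1, ~0.96 at CV 0.02 on the default
  conditions); single-time persistence fractions and the paired test are
  the sensitive readouts.
- Protein inference is taken at face value: records are grouped by the
  accession supplied, with no handling of shared peptides.
- Spectral-count enrichment with three replicates has limited power;
  the volcano quantities are descriptive, and the uncorrected α = 0.05
  flags ~5% of true-null common interactors by construction.
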