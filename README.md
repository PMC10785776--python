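# pulsechase

Downstream analysis for SILAC pulse-chase protein turnover experiments in
postmitotic cells, plus spectral-count filtering for IP-MS interactome
studies. Written for proteomics researchers who have already run database
search and peptide quantification and need the bespoke steps that follow:
labeling-efficiency summaries, protein-level turnover ratios with the
standard filters, cross-genotype "persisting protein" calls, first-order
rate fits, and IgG-controlled interactor scoring.

## The science in brief

**Turnover.** Cells are pulsed with heavy lysine/arginine until the
proteome reaches a labeled fraction *E* (~90%), then chased with light
medium. Pre-existing (heavy) protein decays while new (light) protein
replaces it; because the cells are postmitotic there is no dilution by
division, so for protein *p* with degradation rate constant *k* the
anchored heavy ratio follows first-order kinetics:

```
R(t) = heavy(t) / heavy(0) = exp(-k t),     half-life = ln 2 / k
```

Peptide MS1 areas are averaged per protein (singletons included); a protein
needs a chase-day-0 anchor plus at least one later time point; individual
ratios ≥ 1 are discarded as artifacts. A protein *persists* in the mutant
genotype at time *t* when both genotypes hold a ratio there and the mutant
ratio is strictly higher — i.e. the protein is degraded more slowly in the
mutant. Rates are estimated by the through-origin log-linear fit
`k = Σ(-t·ln R) / Σ t²`.

**Interactome.** Each IP replicate pairs a bait (VCP) run with a
nonspecific-IgG control. A protein passes a replicate if it co-precipitates
exclusively with the bait (absent from IgG) or its raw VCP/IgG spectral
count ratio is strictly greater than 3; it is a genuine interactor for a
genotype only if it passes in **all** replicates. Interactor sets are then
partitioned into mutant-only / control-only / common, and common
interactors are tested for genotype enrichment with per-protein unpaired
t-tests on bait-normalized counts.

A synthetic-data generator emulates both experiments with known ground
truth (rates, slowed proteins, interactor labels), so every stage has a
parameter-recovery test surface.

## Worked example

```
$ python analysis/01_simulate.py
peptide rows:          22084  (proteins: 500)
spectral-count rows:     907  (replicates: 3 per genotype)

$ python analysis/03_turnover.py
protein x genotype profiles: 999
day    1: 336 common proteins | persisting  54.2% | mean R mut 0.785 vs ctrl 0.773 | paired p 8.50e-02
day    5: 465 common proteins | persisting  53.5% | mean R mut 0.503 vs ctrl 0.476 | paired p 5.38e-06
day   21: 499 common proteins | persisting  59.3% | mean R mut 0.185 vs ctrl 0.160 | paired p 6.78e-11
persist at all three times: 102 proteins

$ python analysis/04_kinetics.py
fitted 999 protein x genotype rate constants
median half-life:        5.73 days
median |k_hat - k| / k:  3.72%
slowed proteins: fitted mutant/control rate ratio 0.50 (truth 0.50)
```

Reading this: the generator slowed 20% of proteins to half rate in the
mutant, so across common proteins the mutant keeps a higher heavy fraction
(0.503 vs 0.476 at day 5), the persisting fraction sits above the 50%
tie-breaking baseline at every time, and the paired test becomes
overwhelming as decay separates the genotypes. The whole peptide → protein
→ ratio → fit chain recovers rate constants to ~4% median error, and the
fitted mutant/control ratio for slowed proteins lands on the true 0.5.
Fewer proteins are common at day 1 than at day 21 — early in the chase the
true decay is small, so noisy ratios more often exceed 1 and get filtered.

The interactome stage (`analysis/05_interactome.py`) recovers 92.7% of
true interactors with zero background false positives on the default
simulation. The same stages are available as a console tool:

```
pulsechase run-all --config configs/demo.yaml --out results/demo
pulsechase simulate turnover --seed 1 --out results/sim
pulsechase interactome --counts results/sim/speccounts.tsv --out results/int
```

## Layout

```
src/pulsechase/   library: tables_io, synthetic_data, labeling, turnover,
                  kinetics, interactome, pipeline, cli
analysis/         numbered narrative drivers writing under results/
tests/            pytest suite incl. brute-force oracle comparisons
docs/methods.md   model, defaults and design choices in detail
```
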