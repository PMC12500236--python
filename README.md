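# newsecm

Quantitative analysis of chemoselectively enriched **newly synthesized
extracellular matrix (newsECM)** proteomes, with the accompanying
immunofluorescence tissue-map quantification.

## The problem

Cells remodel their extracellular matrix continuously, but new ECM
deposition is hard to see: bulk proteomics of an ECM extract is dominated
by pre-existing, high-abundance structural proteins.  A chemoselective
strategy fixes this by metabolically labeling newly synthesized
glycoproteins with an azido sugar (Ac4GalNAz), conjugating the azide to
desthiobiotin, and enriching on streptavidin.  Label-free LC-MS/MS of the
fractions before ("inputs", bulk ECM) and after ("eluates", enriched
newsECM) the pull-down then requires a specific statistical workflow, which
this package implements for proteomics analysts working with such data:

* **total-intensity normalization** — `X_Ki,norm = X_Ki,orig x
  Sum_average / Sum_Ki` within configurable sample groups; detection
  prefilter (≥ 2 nonzero values per comparison group); Grubbs outlier
  tests (α = 0.05);
* **left-censored imputation (QRILC)** — per-sample quantile regression of
  the observed log2 tail against standard-normal quantiles estimates the
  complete-data (μ, σ); missing values are drawn from a normal truncated
  above at the estimated censoring point;
* **differential statistics** — two-tailed Welch t-tests, permutation-based
  FDR (q values exact under exhaustive permutation), geometric-mean fold
  changes (`log2 FC = mean log2 A − mean log2 B`), volcano classification
  at `|log2 FC| > 1, q < 0.05` with boundaries non-significant, Pearson
  correlation matrices;
* **enrichment quality control** — labeled/vehicle fold ratios of protein
  groups and intensities, human/rat species recovery
  (`100 x eluate sum / input sum`), actin/tubulin/histone contaminant
  shares, matrisome category composition of eluates vs inputs;
* **image quantification** — the "DAPI map": nuclear-channel contrast
  stretch → threshold → size filtration → disk closing gives a binary
  tissue mask; signal channels are averaged inside/outside by logical
  indexing and normalized by tissue area or a reference channel;
* **a calibrated synthetic-data generator** — lognormal abundances with
  configurable replicate-correlation structure, missing-not-at-random
  left-censoring, two-mechanism labeled/vehicle enrichment, species
  mixtures and matrisome composition shifts, plus synthetic fluorescence
  fields with known tissue masks — so every stage is verifiable against
  ground truth without the deposited raw data.

## Worked example

Generate the dECM-tumor study arm (5 labeled vs 3 vehicle eluates plus
inputs, 2000 proteins, mixed human/rat) and audit the enrichment:

```python
from newsecm import decm_tumor_preset, generate_proteome_dataset, run_enrichment_qc

table, truth = generate_proteome_dataset(decm_tumor_preset(seed=1))
report = run_enrichment_qc(table)
```

`python examples/enrichment_qc.py` runs exactly this and prints:

```
protein-group fold (labeled/vehicle): 5.33
total-intensity fold (labeled/vehicle): 23.09

species recovery (eluate vs input):
         recovery_percent  eluate_share_percent
species
human               86.55                 98.83
rat                 29.70                  1.17

contaminant share of input intensity: 0.362%
```

The labeled eluates carry ~5.3x more identified protein groups and ~23x
more total intensity than vehicle controls — the chemoselective capture
works; human proteins (made by the labeled tumor cells) are recovered at
~87% of their input level while rat proteins (pre-existing scaffold) drop
to ~30% and only ~1.2% of eluate signal — the enrichment is selective for
*new* synthesis; and intracellular contaminants are ~0.4% of input — the
ECM extraction is clean.  `examples/` holds one narrative script per
capability (simulation, QC, differential analysis, matrisome composition,
image quantification); each prints the numbers above alongside an
explanation.

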