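# mockbench

Benchmarking and reproducibility statistics for **species-level 16S rRNA
amplicon profiles**.

Microbiome sequencing runs routinely carry positive controls — mock
communities with a known composition, such as the 8-species ZymoBIOMICS
standard — alongside negative controls, technical replicate pairs, and
paired collection methods (stool vs rectal swab). `mockbench` turns those
controls into numbers: how accurately a wet-lab + bioinformatics protocol
recovers known species, how contaminated the plates are, and how
reproducible whole community profiles are between replicates. It is aimed
at groups validating an amplicon protocol before committing a clinical or
cohort study to it.

## What it computes

**Mock-control accuracy** (`mockbench.mock_eval`). With TP = expected
species detected at species rank, FN = expected species missed and FP =
unexpected species-rank taxa:

```
precision = TP / (TP + FP)
sensitivity = TP / (TP + FN)
F = 2 · precision · sensitivity / (precision + sensitivity)
```

plus, per species, the observed/expected abundance ratio
O/E = observed % / theoretical % (1 = unbiased recovery, 0 = missed), and
the percent of each profile correctly classified as an expected species.
Species missed at species rank but present at genus rank are reported as
*genus rescues*, never as true positives.

**Contaminant filtering** (`mockbench.preprocess`). Plate-wise scoring of
each taxon against the plate's own negative controls: a one-sided Fisher
exact test on presence in negatives vs real samples (prevalence channel),
optionally combined — via Fisher's method — with a one-sided Spearman test
of relative frequency against inverse input-DNA concentration (frequency
channel). Taxa scoring below a threshold (default 0.1) are removed.
Median library-size normalization rescales every sample to the median
library total, preserving within-sample proportions.

**Diversity** (`mockbench.diversity`). Observed richness, Shannon entropy
(−Σ p ln p, natural log) and Gini–Simpson (1 − Σ p²) per sample;
Bray–Curtis (Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)) and presence/absence Jaccard distances
between samples, at any taxonomic rank.

**Reproducibility** (`mockbench.reproducibility`). For paired designs
(within-run / between-run technical replicates, stool/swab pairs):
two-sided paired Wilcoxon signed-rank tests with 95% Hodges–Lehmann
confidence intervals on alpha diversity, and a **distance-based
intraclass correlation coefficient (dICC)** on beta-diversity matrices:

```
dICC = 1 − mean d(a,b)² over pairs / mean d(i,j)² over cross-pair sample pairs
```

which is 1 for perfectly duplicated pairs, ≈0 for uninformative pairing,
and reduces to the classical one-way ICC σ_b²/(σ_b²+σ_w²) under Euclidean
distance. Bands: <0.5 poor, 0.5–0.75 moderate, ≥0.75 good.

**Synthetic data** (`mockbench.synthetic`). Seeded generators for every
input: mock controls with compositional noise, species dropout (with
genus rescue) and low-abundance spurious taxa; replicate pairs from a
variance-components model with known ICC; and full plates with planted
reagent contaminants — each with a truth record for oracle testing.

## Worked example

`python examples/score_mock_controls.py` scores the bundled extraction
(whole-cell) mock-control profiles of the 8-species standard:

```
control        TP FP FN  precision sensitivity F   %correct
R1P1Zymoex      7 15  1       0.32        0.88 0.47    80.84
R1P2Zymoex      8  3  0       0.73        1.00 0.84    99.66
...
median F-score 0.84 (range 0.47-1.00)

species                          theoretical%  O/E median (range)
Limosilactobacillus fermentum           18.4  0.98 (0.90–1.01)
Bacillus subtilis                       17.4  1.07 (0.00–1.13)
Listeria monocytogenes                  14.1  0.32 (0.00–0.35)
...
```

Reading this: the first control detected 7 of 8 expected species (the
miss was *Bacillus subtilis*, a hard-to-lyse gram-positive) and picked up
15 spurious low-abundance taxa, so precision is poor (0.32) even though
80.84% of its reads were still assigned to expected species. *Listeria
monocytogenes* was recovered at roughly a third of its true abundance in
every control (O/E median 0.32) — an extraction bias — while the 0.00 in
the *B. subtilis* range marks the controls that missed it entirely.

The other examples cover contaminant filtering
(`examples/decontaminate_plate.py`), diversity measures
(`examples/diversity_basics.py`) and replicate statistics
(`examples/replicate_reproducibility.py`). The same capabilities are
available from the shell via the `mockbench` CLI
(`simulate` / `decontam` / `diversity` / `eval-mocks` / `repro`).

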