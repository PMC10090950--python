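# trail

Turnover and replication analysis by isotope labeling: joint estimation
of **protein turnover rates** and **cell-division rates** from ¹⁵N
metabolic-labeling time courses, yielding cell-cycle-corrected protein
degradation rates and comparative lifetime statistics across tissues and
multiprotein complexes.

## The problem

In a living tissue, the apparent turnover of a protein mixes two
processes: proteolytic degradation and dilution as cells divide.
Feeding mice ¹⁵N-labeled chow labels both newly made proteins and newly
replicated DNA, so a single labeling experiment can separate the two.
`trail` implements the analysis side of that design:

- **k_t** — the observed clearance rate of a protein, fit from the decay
  of its unlabeled TMT reporter signal over a multi-day time course with
  the model `y(t) = b + (1 − b)·e^(−k_t·t)`;
- **k_div** — the cell-division rate, inferred from the ¹⁵N isotopologue
  spectra of mono- and dinucleotides digested from genomic DNA. The
  dinucleotide envelope (the self-convolution of the precursor-pool
  distribution) separates genuinely old strands from new strands built
  with recycled unlabeled nucleotides;
- **k_deg = k_t − k_div** — the cell-cycle-corrected degradation rate,
  with proteins where `k_t ≤ k_div` flagged as division-dominated
  (cleared by dilution, not proteolysis);
- comparative statistics: variance-to-mean dispersion of rates across
  tissues (D) and within complexes (d), random-subset nulls, Welch-type
  per-protein cross-tissue tests, and Spearman correlation of turnover
  with sequence features (GRAVY, pI, polar mole %, long disordered
  regions).

It is aimed at proteomics groups running ¹⁵N/TMT (SILAM-style) labeling
studies who need a reproducible path from extracted reporter and
isotopologue intensity tables to corrected rate constants.

## Worked example

Simulate a small labeled tissue and recover its rates end to end:

```python
import numpy as np
from trail import (SimConfig, DnaSimConfig, simulate_proteome_timecourse,
                   simulate_dna_labeling, process_reporter_table,
                   analyze_dna_table, correct_kdeg)

# a proliferative tissue: 3-day doubling time, median protein t1/2 ~1.7 d
table, truth = simulate_proteome_timecourse(
    SimConfig(n_proteins=200, rate_space="k_t", rate_median=np.log(2)/1.7,
              k_div=np.log(2)/3, noise_sigma=0.02, seed=1))
fits = process_reporter_table(table)

dna, _ = simulate_dna_labeling(
    DnaSimConfig(k_div=np.log(2)/3, noise_sigma=0.01, seed=2))
div, _ = analyze_dna_table(dna)

print(f"doubling time: {div.doubling_time.iat[0]:.2f} d")
print(f"median protein half-life: {fits[fits.passed].t_half.median():.2f} d")
corr = correct_kdeg(fits.k_t.iat[0], div.k_div.iat[0])
print(f"first protein: k_deg = {corr.k_deg:.3f}/d, "
      f"division-dominated: {corr.division_dominated}")
```

Output:

```
doubling time: 3.00 d
median protein half-life: 1.70 d
first protein: k_deg = 0.267/d, division-dominated: False
```

The doubling time comes back at the simulated 3 days, the median fitted
half-life sits at the simulated ~1.7 days, and the first protein's
turnover clearly outpaces dilution.

The same pipeline is exposed as a CLI over delimited-text tables:

```bash
trail simulate proteome --out sim --seed 1
trail fit-protein --input sim/reporter_table.tsv --out fits
trail simulate dna --out dna --seed 2
trail fit-dna --input dna/isotopologue_table.tsv --out div
```

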