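# cytoinfo

Information-theoretic analysis of single-cell cytokine signalling data.

Cells of the same type express signalling proteins at very different
levels, yet pathways like IL-6-induced JAK/STAT manage to transmit dose
information reliably. `cytoinfo` quantifies two sides of that question on
multiplexed flow-cytometry data (per cell: total STAT3 expression, STAT3
pY705 phospho-response, plus dose/time/replicate/line metadata):

* **Robustness** — the mutual information between a cell's STAT3
  expression `S` and its phospho-response `R` at a fixed dose,

  ```
  MI(S; R) = ∬ p(S,R) · log₂[ p(S,R) / (p(S)·p(R)) ] dS dR   (bits),
  ```

  estimated by Gaussian-kernel density estimation and numerical
  integration. Low MI means the response is insensitive to expression
  heterogeneity (robust); MI rising with dose means the available STAT3
  becomes limiting.

* **Channel capacity** — the maximum of MI(dose; response) over input
  distributions on the applied dose set, `CC = max_{p(S)} MI(S;R)`;
  `2^CC` is the number of dose levels the response can reliably
  distinguish. Two estimators are provided: an exact Blahut–Arimoto
  solver on a quantile-discretised channel, and a statistical-learning
  estimator (regularised multinomial logistic classifier + Monte-Carlo
  Blahut–Arimoto on its posteriors) for continuous and multivariate
  responses. `capacity_var` additionally hands the decoder the
  stimulus-independent expression covariate, removing the blur that
  expression heterogeneity adds to the dose-response mapping.

Population operations from the assay are included — per-experiment
normalisation of maximal mean fluorescence to 100 %, tail gating of
extreme expressers, symmetric truncation of expression heterogeneity to a
residual fraction — together with FCS 3.0/3.1 and tidy-CSV I/O and a
synthetic flow-cytometry generator so every analysis is testable without
external data.

## Worked example

```python
from cytoinfo import (SimulationConfig, simulate_dataset, mi_dose_sweep,
                      summarize_mi_by_dose, ChannelDataset,
                      capacity_basic, capacity_var, truncation_capacity_sweep)

# synthetic MEF-like experiment: 12 doses, 3 replicates, 2,000 cells each
cells, _ = simulate_dataset(SimulationConfig(n_cells=2000, n_replicates=3, seed=1))

# robustness: MI(expression; response) per (replicate, dose), then summarised
summary = summarize_mi_by_dose(mi_dose_sweep(cells))
print(summary[["dose", "mi_median"]].tail(3))

# capacity with and without heterogeneity truncation
sweep = truncation_capacity_sweep(cells, (1.0, 0.15))
print(sweep.groupby("residual")[["capacity_basic", "capacity_var"]].mean())
```

At seed 1 this prints a median MI of 0.007 bits at the lowest stimulated
dose (0.5 ng/ml) rising to 0.917 bits at 200 ng/ml — the response is
robust to expression variability only while doses are low — and

```
          capacity_basic  capacity_var
residual
0.15            1.051         1.055
1.00            0.817         0.969
```

i.e. the full heterogeneous population transmits ~0.8 bits (barely two
distinguishable dose states); excluding extreme expressers down to 15 %
residual variability raises the basic capacity to ~1.05 bits, while the
covariate-aware capacity is already at that level and stays flat —
expression heterogeneity itself is what limits the channel.

The same analyses are available from the shell:

```bash
cytoinfo simulate --out cells.csv --seed 1 --n-cells 2000
cytoinfo mi cells.csv
cytoinfo capacity cells.csv
cytoinfo sweep cells.csv --residuals 1.0,0.5,0.15
```

`cytoinfo reproduce --data-dir <path>` re-runs the capacity analysis on a
locally provided deposited dataset and reports the computed capacities
alongside the published reference values; it skips cleanly when the data
are not present.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch — the MI-vs-dose
sweep and the truncation/capacity analysis on a freshly generated
synthetic dataset — prints them, and writes the results JSON.

See `docs/methods.md` for the estimators' assumptions, the generative
model behind the synthetic data, and numerical choices.
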