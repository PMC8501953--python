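# dropgate

Analytics for droplet single-cell RNA profiling. Cells are encapsulated
in picolitre droplets with an isothermal amplification assay (RT-LAMP);
each droplet transiting a laser produces a fluorescence plateau in a
multi-channel photodetector trace, and per-marker amplification is read
out as a fold change over the empty-droplet background. `dropgate`
implements the complete computational layer of such an experiment for
people building or analysing these assays:

- **`dropgate.simulate`** — a generative model of the assay (Poisson cell
  loading at ~1 cell per 10 droplets, per-marker amplification
  probabilities, spectral crosstalk, detector noise, nucleus-spike
  artifacts) producing event tables and raw traces with ground truth.
- **`dropgate.trace`** — fixed-threshold event detection: maximal runs of
  above-threshold samples become droplet events with a duration and
  per-channel mean fluorescence.
- **`dropgate.gating`** — the gating cascade: linear spillover
  compensation, a duration (size) gate trimming 8% per tail, a
  stain-channel cell gate, down-sampling to 10,000 events, an
  amplification threshold at 2.8× the empty-droplet median, per-marker
  classification, percent-positive and two-marker quadrant counts.
- **`dropgate.rarecell`** — the binomial detectability model. With
  per-cell true/false positive rates TPR and FPR, a mixture of `n` cells
  at positive-cell prevalence `q` yields an expected positive count
  `E[K] = n(1−q)·FPR + nq·TPR`; detection is the exact one-sided test of
  `round(E[K])` against the null Binomial(n, FPR). Limit-of-detection
  grids and simulated mixture-linearity series included.
- **`dropgate.logic`** — DNA strand-displacement logic (YES, NOT, OR,
  AND, AND-NOT gates; multi-level circuits; expression parser; Boolean
  and equilibrium signal-level evaluation).
- **`dropgate.enrichment`** — efficiency-corrected fold enrichment from
  qPCR threshold cycles,
  `E = (1+E_R)^(Ct_R,sorted − Ct_R,initial) · (1+E_X)^(Ct_X,initial − Ct_X,sorted)`,
  plus standard-curve efficiency estimation from dilution series.

## Worked example

```python
from dropgate import (AssayModel, CellClass, GateConfig, DetectionDesign,
                      detection_pvalue, min_detectable_prevalence,
                      run_gating, simulate_event_table)

# 10% marker-positive cells (TPR 0.971) in a negative background
model = AssayModel(
    classes=[CellClass("pos", {"FAM": 0.971}), CellClass("neg", {"FAM": 0.0002})],
    proportions=[0.1, 0.9], seed=1,
)
events, truth = simulate_event_table(model, 100_000)
report = run_gating(events, GateConfig())
print(f"cells analyzed: {report['n_analyzed']}")
print(f"FAM threshold:  {report['thresholds']['FAM']:.1f}")
print(f"percent FAM+:   {100 * report['percent_positive']['FAM']:.2f}%")

d = DetectionDesign(n_total=10_000, prevalence=0.001, tpr=0.971, fpr=2e-4)
print(f"0.1% spike-in, 10,000 cells: p = {detection_pvalue(d):.2e}")
print(f"LOD at 100,000 cells: {min_detectable_prevalence(100_000)}")
```

prints

```
cells analyzed: 8357
FAM threshold:  280.0
percent FAM+:   10.61%
0.1% spike-in, 10,000 cells: p = 1.36e-06
LOD at 100,000 cells: 0.0001
```

The gated positive fraction recovers the mixture composition times the
assay TPR (0.1 × 0.971 ≈ 9.7%, nudged upward here because droplets
holding two cells report the OR of their cells' marker states); a
1-in-1,000 spike-in is detectable with 10,000 cells, and 100,000 cells
push the limit of detection to 1 in 10,000.

The same functionality is exposed on the command line:

```bash
dropgate logic --expr "(KRT19 OR VIM) AND-NOT PTPRC"
dropgate rarecell-power --n 10000,100000
dropgate enrich --ct ct.csv --eff-target 0.17 --eff-ref 0.36
dropgate run --config config.yaml --out report.csv
```

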