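# odcell

Tools for converting OD600-referenced *E. coli* measurements into per-cell
quantities. The package bundles:

- **`odcell.reference`** — an embedded 24-condition reference table of growth
  rate, cell length/width, single-cell volume, OD-specific cell concentration
  and OD-specific total cell volume, plus the shared physical constants
  (fixed mean width 1.26 µm, total volume ≈3.6 µl·ml⁻¹·OD⁻¹, 0.092 µm/pixel,
  7 µm counting beads, 20+380 µl tube layout).
- **`odcell.morphometry`** — segmentation of rod cells / beads from
  single-channel images, principal-axis length/width measurement, and the
  capped-cylinder volume model `V = π·w²·(l − w/3)/4`, with a fixed-width or
  per-cell-width population summary (≥200-cell rule).
- **`odcell.cytometry`** — threshold gating of FSC/SSC/FL1 event tables,
  bead-referenced absolute cell concentration (analyzed volume inferred from
  the bead fraction; optional 400/380 aliquot correction; Poisson counting
  error), and linear scatter→volume calibration with prediction intervals.
- **`odcell.growth`** — a polynomial fit of cell volume against log10(growth
  rate) (stationary cells mapped to a pseudo-rate of 0.1), the total-volume
  constant, and reciprocal-model predictions of cell concentration from OD
  and growth rate.
- **`odcell.conversion`** — conversion of amounts in mol·ml⁻¹·OD⁻¹ into
  copies per cell (`amount·N_A/N`) and intracellular molar concentration
  (`amount/(V_tot·10⁻⁶ L)`), with Monte Carlo or delta-method uncertainty
  propagation, plus a monotone (PCHIP, log-log) OD non-linearity correction.
- **`odcell.synthetic`** — deterministic generators for microscopy images
  (stadium-shaped cells, disk beads, Gaussian PSF and noise, exact ground
  truth), cytometry event tables (Poisson counts, log-normal channels),
  OD calibration pairs and omics tables, so the full chain is testable
  without any external data.

## CLI

```sh
odcell reference --out table.csv
odcell measure --images 'imgs/*.tiff' --pixel-um 0.092 --out summary.csv
odcell count --events events.csv --beads-total 20000 --dilution 500 --od 0.5
odcell fit --model volume --degree 2 --out volume.yaml
odcell convert --omics omics.csv --condition glucose --mc 10000 --seed 1 --out converted.csv
odcell simulate --kind beads --spec spec.yaml --out-prefix beads
```

Event tables are plain CSV with `FSC,SSC,FL1` columns; gates are YAML with
log10 bounds (see `tests/test_cli.py` for the schema). Fitted models are
re-derivations from the embedded table, not published parameterisations,
and are labelled as such in their YAML output.

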