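# infiltra

A tested, reusable pipeline for quantifying immune infiltration in lesion
tissue images and screening a driver-mutation neopeptide, exercised
end-to-end on synthetic data with known ground truth. It covers:

- **`infiltra.synthgen`** — synthetic inputs for every stage: fluorescence
  lesion images rendered as non-overlapping colored disks with exact
  pixel-level ground truth, patient cohorts (lognormal CD8:CD1a ratios with
  group-specific medians, HLA genotypes, right-censored event times),
  simulated human counters, 4-parameter-logistic binding titrations, and
  PRM light/heavy transition reports. Every generator is a pure function of
  (spec, seed).
- **`infiltra.image_quant`** — automated digital image analysis: polygon ROI
  restriction, per-image affine white balance from designated
  background/foreground/autofluorescence pixels, uniform HSV color
  thresholds for the green/red/purple stain classes, cumulative area
  measurement, and (red+purple)/green and purple/green area ratios.
- **`infiltra.density_quant`** — the manual-counting workflow: per-image
  count aggregation, two-counter adjudication (>10% discrepancy triggers a
  referee), density ratios with the "1 T cell per N lesion cells"
  reciprocal, 1+–4+ semi-quantitative scoring with consensus rules, and
  cross-method Spearman concordance.
- **`infiltra.hla_assoc`** — carrier (dominant) case-control association:
  2×2 carrier tables, exact Hardy-Weinberg testing, two-sided Fisher exact
  tests, Šidák correction (per-locus families), Woolf odds ratios with the
  Haldane correction, and p-value standardization to a reference control
  size (cases + 3×cases), capped at 0.5.
- **`infiltra.cohort_stats`** — median split, Mann-Whitney / Fisher group
  comparisons, Kaplan-Meier + log-rank event-free survival, univariate Cox
  on log-transformed ratios, and the stratified characteristics table.
- **`infiltra.pepscreen`** — enumeration of mutation-spanning 8–12mer
  peptides, competition-binding IC50 fitting (4PL) with reference-ratio
  interpretation and binder classification, and PRM light/heavy abundance
  quantitation with detection calls.

## CLI

One entry point with a subcommand group per stage:

```bash
infiltra synth image --out lesion.png --truth-csv truth.csv --seed 7
infiltra synth cohort --out cohort.csv --genotypes-out geno.csv --n-patients 101
infiltra quant auto --images images/ --out areas.csv
infiltra quant manual --counts counts.csv --out ratios.csv
infiltra quant semiquant --scores scores.csv --out consensus.csv
infiltra hla scan --cases cases.csv --controls controls.csv --out scan.csv
infiltra stats table1 --cohort cohort.csv --out table1.csv
infiltra stats survival --cohort cohort.csv --curves-out km.csv
infiltra pep enumerate --fasta protein.fasta --variant "BRAF:p.V600E" --out peps.csv
infiltra pep ic50 --titration curve.csv --reference-ic50 297
infiltra pep prm --report transitions.csv --out detections.csv
```

File formats are plain text throughout: PNG/TIFF images, CSV tables
(documented column names in each subcommand's `--help`), GeoJSON-style ROI
polygons, YAML threshold configs, JSON reports.

## Conventions worth knowing

- Pixels are 0-based, origin top-left; a pixel belongs to an ROI iff its
  center lies strictly inside the polygon.
- Pixel classification assigns at most one class per pixel with priority
  purple > red > green on overlapping hue windows.
- Median splits send values equal to the median to the LOW group.
- Averaged counts and scores round half-up.
- A zero denominator (no green area / no CD1a cells) raises an explicit
  undefined-ratio error instead of silently producing 0.
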