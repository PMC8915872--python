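# inhalttc

A tested, reusable pipeline for deriving inhalation threshold-of-toxicological-
concern (TTC) values from heterogeneous repeat-dose inhalation study records.

The pipeline takes tab-separated study-record tables (one toxicity study per
row, with free-text study types, mixed concentration units and species name
variants) through:

1. **Annotation** — study-length classification (chronic / subchronic /
   subacute / reproductive / developmental / multigenerational) from study-type
   tokens and durations, species normalization to a rodent/other tag, removal
   of ambiguous values (0 / −999), and unit standardization onto parallel
   mg/m³ and ppm tracks (ppm ↔ mg/m³ via molecular weight and a 24.45 L/mol
   molar volume).
2. **Representative-value selection** — per substance and unit track:
   singletons retained, extreme outliers beyond the Tukey fences
   (1.5 × IQR) removed in a single pass, minimum of the survivors returned.
3. **Distribution statistics** — log10 ECDFs, normal-CDF overlays, QQ data,
   Shapiro–Wilk and two-sample Kolmogorov–Smirnov tests, empirical 5th
   percentiles and their bootstrap (10,000 replicates by default).
4. **TTC derivation** — air-concentration TTC (P5 × dexp / 25), body-dose
   NOEL (P5 × dexp × Vresp/bw × 1000) and per-person daily TTC
   (NOEL × bw / 25), with dexp = (6/24)·(5/7), Vresp = 20 m³/day,
   bw = 60 kg; all constants overridable. Plus the tiered decision-tree
   assignment of oral TTC thresholds (0.15 / 18 / 90 / 540 / 1800 µg/day,
   with cohort-of-concern exclusions).
5. **Mode-of-action consensus** — harmonization of three aquatic-MOA
   profiler outcomes into one consensus label (unanimity → majority →
   most-conservative), with confusion-matrix and precision/recall reports.
6. **Cross-dataset comparison** — re-derivation of TTCs from external
   supplementary-style tables, identifier overlap, log-scale Pearson
   correlation and Welch t-tests.

A synthetic data generator (`inhalttc.synth`) produces study-record tables
with known ground truth (hidden in sidecar files) so every stage is testable
without external downloads.

## CLI

The `inhalttc` entry point exposes one subcommand per stage:

```sh
inhalttc synth    --config synth.yaml --out data/ --seed 1
inhalttc annotate --in data/studies.tsv --substances data/substances.tsv --out annotated.tsv
inhalttc collapse --in annotated.tsv --out collapsed.tsv
inhalttc stats    --in grouped.tsv --group-col group --value-col value --out stats/ --seed 1 --reps 10000
inhalttc derive   --in stats/summary.json --out ttc.tsv
inhalttc moa      --in profiler_labels.tsv --out consensus.tsv
inhalttc compare  --a a.tsv --b b.tsv --out cmp/
```

All tables are UTF-8 TSV with a header row. `annotate` writes sidecar
`.rejects.tsv` (rows with unrecognized units or invalid durations) and
`.attrition.tsv` (per-criterion drop counts) files next to its output.

## Layout

```
src/inhalttc/
  constants.py       derivation constants (dexp, uncertainty factor, Vresp, bw)
  synth.py           synthetic study-record generator + ground truth
  annotation.py      study-length / species / unit annotation and filtering
  representative.py  Tukey fencing and minimum selection
  dist_stats.py      ECDF, percentiles, normality tests, K-S, bootstrap
  ttc.py             TTC formulas and tiered decision-tree assignment
  moa.py             profiler-outcome mapping and consensus
  comparison.py      cross-dataset re-derivation and comparison statistics
  cli.py             click-based CLI
```
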