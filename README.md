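# drugcombo

Median-effect dose-response analysis and fixed-ratio drug-combination
synergy quantification, plus a fold-change differential screen — a tested,
scriptable alternative to point-and-click combination-index tools.

## What it does

- **viability** — convert raw MTT OD490 plate readings (sample/control/blank
  wells) into viability %, inhibition %, and fraction affected (fa), with
  mean ± SD replicate aggregation.
- **median_effect** — the median-effect model `fa/fu = (D/Dm)^m`: forward
  curve, inverse dose, and log-linear OLS fitting of (Dm, m) with the
  plot's Pearson r as fit quality. Boundary fa values (0 or 1) are excluded,
  not clamped.
- **combination** — fixed-ratio designs (Dm-proportional weights, serial
  1:1.5-style dilution ladders), the combination index
  `CI = Σ d_j / Dx_j(fa)` under Loewe additivity, Fa–CI curves, and verdict
  classification on half-open CI bands (very strong synergism … strong
  antagonism) that tile (0, ∞).
- **synthetic** — generators for single-drug curves, fixed-ratio mixtures
  with a prescribed true CI profile κ (constant or tabulated in fa), raw
  OD plate rows, and planted differential protein tables. Fully seeded, so
  every stage of the pipeline is testable against known ground truth.
- **screen** — strict fold-change filtering (>1.5 up, <0.67 down),
  hypergeometric term enrichment with Benjamini–Hochberg adjustment
  (optional EASE mode), and PPI network degree ranking from edge lists.
- **pipeline / cli** — an end-to-end `run` command producing single-drug fit
  tables, the mixture fit on total dose, a CI table with verdicts (2-decimal
  display + full-precision companion), the Fa–CI curve, and a JSON run
  manifest. Re-running with the same inputs and seed is byte-identical.

## CLI

Each stage is independently invocable:

```sh
drugcombo fit -i singles.csv -o fits.csv          # per-drug Dm, m, r
drugcombo design --fits fits.csv -o design.json   # fixed-ratio ladder
drugcombo ci --fits fits.csv --combo combo.csv -o ci_table.csv
drugcombo curve --fits fits.csv --combo combo.csv -o fa_ci.csv
drugcombo simulate single|combination|proteins ...
drugcombo screen filter|enrich|degree ...
drugcombo run --config run.yaml                   # full pipeline
```

Input formats (UTF-8 CSV, dot decimal, header required):

- single-drug points: `drug,dose,unit,fa`
- plate readings: `drug,dose,unit,replicate,role,od490` with role in
  {sample, control, blank}
- combination observations: one dose column per component plus `fa`
- protein quantities: `id,fold_change`; term maps and edge lists are
  two-column TSV

A minimal simulation config (YAML):

```yaml
drugs:
  - {name: A, dm: 6.54, m: 2.0}
  - {name: B, dm: 5.53, m: 1.8}
  - {name: C, dm: 7.88, m: 2.2}
true_ci: 0.27
sigma: 0.02
replicates: 3
seed: 1
```

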