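# fcki — hybrid hot-deck imputation for numeric tabular data

Missing values are endemic in biostatistical and epidemiological tables, and
most downstream models silently assume complete data. `fcki` implements two
hybrid hot-deck imputation methods for numeric rectangular datasets:

* **KI** — for each incomplete record R_i, build the donor pool P of records
  observed on all of R_i's missing attributes A_mis, choose the neighbour
  count k automatically by a self-probe (withhold one observed value r_iz,
  score every k ∈ [2, N_p − 1] by the error |AV − r̂_iz| of the k-donor mean
  estimate, keep the arg-min), take the k nearest donors d_k under a
  missing-aware Euclidean distance, and impute R_i by round-robin
  regression over the small subset S = d_k ∪ {R_i}. Imputed records rejoin
  the dataset immediately and can serve as donors for later records.
* **FCKI** — first partition the (still incomplete) dataset into c fuzzy
  clusters by fuzzy c-means, minimising
  J = Σ_i Σ_k δ_ik^{m′} ‖R_i − c_k‖², with c picked at the elbow of the
  J(c) curve; each record is routed to its highest-membership cluster and
  KI runs within each cluster separately. With a single cluster FCKI is
  exactly KI.

Neither method needs a single fully complete record: donors only have to be
complete on the attributes the recipient is missing, and all distances use
the partial-distance convention (co-observed squared differences rescaled
by M/m_obs).

The package also provides everything needed to evaluate such methods:

* missingness generators for the three standard mechanisms — MCAR, MAR
  (rows with the smallest values of a random causative attribute lose
  values in random dependent attributes) and MNAR — at a target percentage
  of all N×M cells;
* masked-cell error metrics RMSE, NRMSE and MAE;
* a benchmark harness running the 3-mechanism × 4-ratio (1, 5, 10, 20 %)
  grid with mean-imputation and global kNNI baselines;
* a seeded synthetic generator (correlated Gaussian mixtures with
  configurable cluster separation, per-cluster dependence orientation and
  feature correlation).

All imputers are scikit-learn style transformers (`KIImputer`,
`FCKIImputer`, `MeanImputer`, `GlobalKNNImputer`, plus `RoundRobinImputer`,
`FuzzyCMeans` and `MissingnessAmputer`) and compose with sklearn pipelines;
thin functions (`ki_impute`, `fcki_impute`, …) wrap them for dataset-level
use.

## Worked example

```python
import numpy as np
from fcki import (MissingSpec, SyntheticSpec, evaluate_masked, fcki_impute,
                  generate_mcar, make_synthetic, mean_impute)

data, _ = make_synthetic(SyntheticSpec(n=200, m=6, n_clusters=2, separation=8,
                                       correlation=0.8, seed=42))
masked = generate_mcar(data, MissingSpec("MCAR", mdr_percent=10, seed=7))
print(f"masked cells: {masked.mask.mv_count} ({masked.mask.ratio_percent:.1f}%)")

result = fcki_impute(masked.data, seed=7)
report = evaluate_masked(masked.truth, masked.mask, result.imputed)
print(f"FCKI  rmse={report.rmse:.4f}  nrmse={report.nrmse:.4f}  mae={report.mae:.4f}")

baseline = evaluate_masked(masked.truth, masked.mask, mean_impute(masked.data).imputed)
print(f"mean  rmse={baseline.rmse:.4f}  nrmse={baseline.nrmse:.4f}  mae={baseline.mae:.4f}")
```

prints

```
masked cells: 120 (10.0%)
FCKI  rmse=0.5739  nrmse=0.0621  mae=0.4405
mean  rmse=2.1267  nrmse=0.2301  mae=1.8346
```

120 of the 1200 cells were removed completely at random; FCKI reconstructs
them with roughly a quarter of the error of column-mean imputation because
it exploits both record similarity (donor selection within the record's own
cluster) and the correlation among features (the regression step). NRMSE is
RMSE divided by the range of the true values at the masked positions, so
0.062 means the typical error is about 6 % of that range.

The same operations are available from the shell:

```sh
fcki generate --mechanism mcar --ratio 10 --seed 7 --in d.csv --out dm.csv --truth-out truth.csv
fcki impute   --method fcki --seed 7 --in dm.csv --out imputed.csv --log run.jsonl
fcki benchmark --in d.csv --methods mean,knni,ki,fcki --seed 1 --out table.csv
```

## Layout

| module | contents |
| --- | --- |
| `fcki.dataset` | `NumericDataset`, mask/provenance types, CSV I/O |
| `fcki.amputation` | MCAR/MAR/MNAR generators |
| `fcki.neighbors` | partial distance, kNN search, automatic k selection |
| `fcki.iterative` | round-robin regression imputation |
| `fcki.fuzzy` | fuzzy c-means on incomplete data, elbow selection |
| `fcki.impute` | `KIImputer`, `FCKIImputer`, baselines |
| `fcki.metrics`, `fcki.benchmark` | masked-cell metrics, grid harness |
| `fcki.synthetic` | correlated Gaussian-mixture generator |
| `fcki.cli` | `fcki generate / impute / benchmark` |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
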