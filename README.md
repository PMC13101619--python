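# carenet

Partial-correlation network analysis of routinely documented care-activity
time data.

## The problem

Hospitals that use a standardized care-activity catalog (LEP-style systems)
document, for every inpatient case, *which* nursing/midwifery activity was
applied, *when*, and *for how many minutes*. Summed over a stay, these
records describe the case's care demand in fine detail — but staffing tools
usually collapse them into a single workload number. `carenet` instead treats
the activities as a system: it estimates which activities' per-stay care
times rise and fall together *conditionally on all the others*, and
characterizes the resulting network of care bundles. The intended users are
health-services researchers and ward-analytics teams working with
care-activity exports from electronic health records.

## The model

Let `X ∈ R^{n×p}` hold the total care minutes of `p` activities over the
stays of `n` cases. The pipeline is the standard regularized Gaussian
graphical model workflow:

1. **Correlation.** `R = corr(X)`, the Pearson correlation of activity
   totals across cases (estimating on the correlation scale standardizes
   activities whose totals span minutes to hundreds of minutes).
2. **Graphical lasso.** The precision (inverse-covariance) estimate

   `Θ̂ = argmax_{Θ ≻ 0}  log det Θ − tr(RΘ) − λ‖Θ‖₁`,  default `λ = 0.05`,

   solved by block coordinate descent with a certified KKT residual. A zero
   `Θ̂ᵢⱼ` means activities *i* and *j* are conditionally independent given
   all the others — their marginal correlation is explained away.
3. **Partial correlations.** `Pᵢⱼ = −Θ̂ᵢⱼ / √(Θ̂ᵢᵢ Θ̂ⱼⱼ)`.
4. **Threshold.** Keep edge `(i, j)` iff `|Pᵢⱼ| ≥ τ` (default `τ = 0.15`,
   inclusive); isolated nodes are removed. Edge weights are the signed
   partial correlations.

The network is then characterized with the standard structural metrics:
degree and (raw) betweenness centralities, diameter and characteristic path
length over connected pairs, density `m / (n(n−1)/2)`, transitivity and
average local clustering, and the modularity `Q = Σ_c (e_c − a_c²)` of a
deterministic greedy community partition.

Because real care-activity datasets are hospital records and not
redistributable, the package ships a synthetic generator
(`carenet.synthetic`) that plants a known block precision structure, draws
zero-inflated log-normal activity totals through a Gaussian copula, and
disaggregates them into timestamped records — plus a Monte-Carlo module
(`carenet.power`) that measures, as a function of sample size, how reliably
the thresholded network recovers the planted edges.

## Worked example

Generate a synthetic maternity-care-like dataset (113 activities, 2 346
cases) and analyze it:

```bash
carenet simulate --seed 1 --outdir demo/sim
# INFO carenet: wrote 364800 records for 2346 cases x 113 activities to demo/sim

carenet analyze --input demo/sim/records.csv --outdir demo/analysis
# INFO carenet: read: 364800 records
# INFO carenet: validate: kept 364800, excluded 0
# INFO carenet: aggregate: 2346 cases x 113 activities
# INFO carenet: filter: kept 113 activities, dropped 0
# INFO carenet: network: 53 nodes, 59 edges (removed 60 isolated activities; glasso 4 sweeps, kkt 3.48e-05)
```

`demo/sim/records.csv` holds one row per documented application:

```
Patient_ID,Care_Activity,Date_Time,N_Provider,Care_Time
C_00000,std_01,2019-06-13 00:38:00,2,2
C_00000,std_01,2019-06-14 02:35:00,1,3
```

`demo/analysis/metrics.json` then contains (excerpt):

```json
{"n_nodes": 53, "n_edges": 59, "density": 0.04, "diameter": 13,
 "characteristic_path_length": 3.76, "global_clustering": 0.35,
 "average_clustering": 0.24, "modularity": 0.81,
 "node_degree": {"median": 2.0, "q25": 1.0, "q75": 3.0, "min": 1.0, "max": 4.0}}
```

Reading: of the 113 simulated activities, 53 survive the partial-correlation
threshold and form a sparse network (4% of possible edges) of small,
strongly separated bundles (modularity 0.81) — the generator's standard-care
and specialized-care backbones plus the isolated discharge module. Median
node degree 2 says a typical retained activity is conditionally tied to two
others. The full per-node/per-edge tables, the GraphML export, and every
intermediate matrix (`correlation.csv`, `precision.csv`,
`partial_correlation.csv`) are written next to it.

A power study over sample sizes:

```bash
carenet power --sizes 250,1000,4000 --reps 20 --seed 0 --outdir demo/power
```

writes `power_summary.csv` with the mean ± Monte-Carlo-SE sensitivity and
specificity of edge recovery per sample size.

## Layout

| module                | contents                                              |
|-----------------------|-------------------------------------------------------|
| `carenet.records`     | record CSV schema, reading/writing, validation rules  |
| `carenet.preprocess`  | case × activity aggregation, filters, duration stats  |
| `carenet.inference`   | Pearson correlation, graphical lasso, partials, thresholding |
| `carenet.metrics`     | centralities, distances, clustering, modularity, report |
| `carenet.synthetic`   | planted ground truths, copula sampler, disaggregation |
| `carenet.power`       | Monte-Carlo edge-recovery study                       |
| `carenet.cli`         | `carenet simulate / analyze / power / report`         |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
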