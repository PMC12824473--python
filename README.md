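# yprofiler

Radiosensitivity phenotyping and transcriptomic profiling for in-vitro
⁹⁰Y-microsphere dose–response screens.

Transarterial radioembolization delivers β-emitting ⁹⁰Y microspheres to
liver tumors, yet response varies widely even at guideline-concordant
absorbed doses, pointing at biological rather than dosimetric heterogeneity.
`yprofiler` implements the analysis chain used to dissect that
heterogeneity in cell-line panels: it turns raw viability readouts measured
over an activity ladder (0–20 MBq/mL) into per-line **normalized AUC (nAUC)**
phenotypes (1 = fully resistant, →0 = sensitive), groups lines by nAUC
Z-score, and links the phenotype to baseline transcriptomes three ways:

- **bootstrap elastic-net stability selection** — genes scored by the
  consistency of their coefficient sign across B bootstrap refits,
  `score = max(freq_pos, freq_neg)`, retained at score ≥ 0.7;
- **nearest-template prediction (NTP)** — per-sample subtype assignment by
  cosine distance to marker-gene templates, with an exact permutation null
  and BH FDR, plus a Kruskal–Wallis test of subtype–nAUC association;
- a transparent **two-group DE summary** (Welch test on log-CPM, FDR < 0.05
  & |log₂FC| > 2 filter, gene-set mean log₂FC reporting).

MIRD-style dosimetry utilities (activity → absorbed dose, ⁹⁰Y decay,
half-life counting) and a ground-truth **synthetic cohort generator**
(plateau-exponential survival curves with closed-form nAUC; negative-binomial
counts with planted phenotype-linked genes) make every stage testable
without external data. Intended users are computational biologists analyzing
radionuclide or radiotherapy screens, and methodologists who need a
reference implementation of sign-frequency stability selection or NTP with a
calibrated permutation null.

## Worked example

Simulate a ten-line cohort with five planted resistance genes, phenotype it,
and recover the genes:

```python
import yprofiler as yp

cohort = yp.simulate_cohort(n_lines=10, n_genes=500, planted=5, seed=42)
reps = yp.replicate_naucs(yp.normalize_viability(cohort.viability))
profile = yp.assign_groups(yp.summarize_nauc(reps))
print(profile.round(3).to_string(index=False))
```

```
cell_line  n  mean_nauc   sem  z_score        group
   LINE00  3      0.112 0.020   -1.542    sensitive
   LINE01  3      0.204 0.007   -1.200    sensitive
   LINE02  3      0.322 0.022   -0.760    sensitive
   LINE03  3      0.393 0.010   -0.497    sensitive
   LINE04  3      0.496 0.014   -0.118 intermediate
   LINE05  3      0.587 0.009    0.221    resistant
   LINE06  3      0.664 0.016    0.507    resistant
   LINE07  3      0.748 0.013    0.821    resistant
   LINE08  3      0.823 0.008    1.099    resistant
   LINE09  3      0.923 0.003    1.468    resistant
```

Each line's mean nAUC is the trapezoid area under its surviving-fraction
curve divided by the flat-100%-survival reference area; SEM is over three
replicates, and the group labels come from the Z-score thresholds (resistant
z ≥ 0, sensitive z ≤ −0.45). Stability selection against the phenotype:

```python
std = yp.standardize_expression(yp.logcpm_transform(cohort.expression))
phen = profile.set_index("cell_line")["mean_nauc"]
scores = yp.bootstrap_stability(std, phen, yp.ENConfig(n_bootstrap=100, seed=0))
hits = yp.select_genes(scores, 0.7)
print(scores.loc[hits].round(3).to_string())
```

```
        freq_pos  freq_neg  score  mean_coefficient  pearson_r  selected
gene
G00002      0.80      0.00   0.80             0.017      0.988      True
G00000      0.78      0.00   0.78             0.017      0.993      True
G00001      0.73      0.00   0.73             0.017      0.989      True
G00021      0.00      0.73   0.73            -0.013     -0.962      True
G00003      0.72      0.00   0.72             0.014      0.981      True
G00004      0.71      0.00   0.71             0.015      0.987      True
```

All five planted genes (G00000–G00004) are recovered with positive sign
frequencies ≥ 0.71 — they are up-regulated with resistance — along with one
background gene (G00021) whose chance anticorrelation with the phenotype
(r = −0.96 at n = 10) makes it statistically indistinguishable from signal.
Dosimetry anchors the ladder to clinical dose units:

```python
>>> yp.mird_dose(20.0)          # top of the ladder, Gy
993.6783...
>>> yp.half_lives_elapsed(240)  # 10-day assay, 64.2 h half-life
3.7383...
```

## Command line

```sh
yprofiler run --seed 1 --out results/          # full synthetic pipeline
yprofiler nauc --viability via.csv --out out/  # phenotyping on your data
yprofiler select --expr expr.tsv --viability via.csv --bootstrap 100
yprofiler classify --expr expr.tsv --signature subtypes.gmt --n-perm 1000
```

Inputs are tidy CSV (viability), TSV genes × samples matrices (expression),
and GMT signatures; outputs are TSV/JSON with `#`-metadata headers and a
manifest of sha256 hashes. Runs are fully reproducible from the single
`--seed`.

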