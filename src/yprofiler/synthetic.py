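"""Synthetic cohorts with known ground truth.

Every downstream stage of the pipeline (nAUC phenotyping, stability
selection, template classification, differential expression) is exercised on
data from this module, so each generator returns its generating truth
alongside the data:

* :func:`simulate_viability` draws noisy survival curves from an
  exponential-decay-to-plateau model and attaches the closed-form nAUC each
  line would have without noise.
* :func:`simulate_expression` draws a negative-binomial count matrix in which
  a planted subset of genes varies linearly (on the log scale) with a
  per-line phenotype.
* :func:`simulate_signature_profiles` builds class-template profiles plus a
  matching marker signature for testing nearest-template classification.

The survival model is V(A) = s + (1-s) * exp(-k A) + noise: a fraction ``s``
of the population is unkillable (the resistant plateau seen at high
activities) and the remainder dies exponentially in activity with rate ``k``.
Its exact nAUC over [0, A_max] is

    nAUC = s + (1-s) * (1 - exp(-k A_max)) / (k A_max)

with the k -> 0 limit equal to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ACTIVITIES",
    "LinePhenotypeParams",
    "SimulatedCohort",
    "closed_form_nauc",
    "simulate_viability",
    "simulate_expression",
    "simulate_signature_profiles",
    "simulate_cohort",
    "write_gmt",
    "read_gmt",
]

#: The assay's standard activity ladder (MBq/mL).
DEFAULT_ACTIVITIES: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 2.0, 4.0, 10.0, 20.0)


@dataclass(frozen=True)
class LinePhenotypeParams:
    """Ground-truth dose-response parameters of one simulated cell line.

    ``plateau`` is the unkillable surviving fraction in [0, 1], ``rate`` the
    per-(MBq/mL) exponential kill constant, ``noise_sd`` the additive Gaussian
    noise on the fraction scale.
    """

    line_id: str
    plateau: float
    rate: float
    noise_sd: float = 0.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau <= 1.0:
            raise ValueError(f"plateau must be in [0,1], got {self.plateau}")
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")


@dataclass
class SimulatedCohort:
    """A complete simulated study: viability + expression + signatures + truth."""

    viability: pd.DataFrame
    expression: pd.DataFrame
    planted_genes: set[str]
    true_nauc: dict[str, float]
    true_labels: dict[str, str]
    signature: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0


def closed_form_nauc(plateau: float, rate: float, a_max: float) -> float:
    """Exact nAUC of the plateau-exponential survival model over [0, a_max]."""
    ka = rate * a_max
    if ka < 1e-12:
        frac = 1.0
    else:
        frac = -np.expm1(-ka) / ka
    return float(plateau + (1.0 - plateau) * frac)


def survival_fraction(params: LinePhenotypeParams, activities: np.ndarray) -> np.ndarray:
    """Noiseless survival fractions of one line over an activity grid."""
    a = np.asarray(activities, dtype=float)
    return params.plateau + (1.0 - params.plateau) * np.exp(-params.rate * a)


def simulate_viability(
    params: list[LinePhenotypeParams],
    activities: tuple[float, ...] = DEFAULT_ACTIVITIES,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw a tidy viability table of noisy survival curves.

    Returns the table (columns cell_line, replicate, activity_mbq_per_ml,
    readout, fraction — readout is the fraction itself, pre-normalized) and a
    map line -> closed-form true nAUC. Noise is additive Gaussian on the
    fraction scale, truncated at 0; the activity-0 point is reported noiseless
    at exactly 1 so normalization is the identity on this table.
    """
    acts = np.asarray(activities, dtype=float)
    if acts.size < 2 or np.any(np.diff(acts) <= 0):
        raise ValueError("activities must be sorted strictly ascending")
    if acts[0] != 0.0:
        raise ValueError("first activity must be 0 (untreated control)")
    if np.any(acts < 0):
        raise ValueError("activities must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, float] = {}
    for p in params:
        clean = survival_fraction(p, acts)
        truth[p.line_id] = closed_form_nauc(p.plateau, p.rate, float(acts[-1]))
        for rep in range(1, p.n_replicates + 1):
            noisy = clean + rng.normal(0.0, p.noise_sd, size=acts.size)
            noisy = np.clip(noisy, 0.0, None)
            noisy[0] = 1.0  # untreated control defines the scale
            for a, f in zip(acts, noisy):
                rows.append(
                    {
                        "cell_line": p.line_id,
                        "replicate": rep,
                        "activity_mbq_per_ml": float(a),
                        "readout": float(f),
                        "fraction": float(f),
                    }
                )
    return pd.DataFrame(rows), truth


def simulate_expression(
    n_genes: int,
    phenotype: dict[str, float],
    planted: int = 5,
    effect: float = 2.0,
    dispersion: float = 0.1,
    depth: float = 1e6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial count matrix with phenotype-linked planted genes.

    Gene-wise log-baselines are Uniform(log 5, log 500); a planted gene g in
    sample i has log-mean baseline_g + ``effect`` * phenotype(i) (phenotype
    centered and scaled to unit SD first, so ``effect`` is a log-fold change
    per phenotype SD). Columns are then rescaled so each sample's expected
    library size is ``depth``. Counts are NB with variance
    mu + ``dispersion`` * mu^2.

    Returns (genes x samples count DataFrame, truth dict with keys
    ``planted_genes``, ``effect``, ``phenotype``).
    """
    if planted >= n_genes:
        raise ValueError("planted must be smaller than n_genes")
    if depth <= 0 or dispersion <= 0:
        raise ValueError("depth and dispersion must be positive")
    values = np.asarray(list(phenotype.values()), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("phenotype values must be finite")
    samples = list(phenotype)
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    planted_genes = set(genes[:planted])
    baseline = rng.uniform(np.log(5.0), np.log(500.0), size=n_genes)
    sd = values.std()
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    log_mu = np.tile(baseline[:, None], (1, len(samples))).astype(float)
    log_mu[:planted, :] += effect * z[None, :]
    mu = np.exp(log_mu)
    mu *= depth / mu.sum(axis=0, keepdims=True)
    n_param = 1.0 / dispersion
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    matrix = pd.DataFrame(counts, index=genes, columns=samples)
    truth = {
        "planted_genes": planted_genes,
        "effect": effect,
        "phenotype": dict(phenotype),
    }
    return matrix, truth


def simulate_signature_profiles(
    classes: list[str],
    markers_per_class: int = 20,
    n_samples_per_class: int = 5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, str]]:
    """Profiles drawn around class templates, plus the matching signature.

    Each class owns ``markers_per_class`` marker genes; a sample of class c is
    the template vector (+1 on c's markers, -1 on every other class's
    markers) plus N(0, noise_sd) on every marker gene.

    Returns (genes x samples profile DataFrame, signature dict
    class -> marker genes, true labels sample -> class).
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if markers_per_class < 1:
        raise ValueError("markers_per_class must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    signature = {
        c: [f"{c}_M{j:03d}" for j in range(markers_per_class)] for c in classes
    }
    genes = [g for c in classes for g in signature[c]]
    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for c in classes:
        template = np.array([1.0 if g in set(signature[c]) else -1.0 for g in genes])
        for i in range(n_samples_per_class):
            name = f"{c}_S{i:02d}"
            columns[name] = template + rng.normal(0.0, noise_sd, size=len(genes))
            labels[name] = c
    profiles = pd.DataFrame(columns, index=genes)
    return profiles, signature, labels


def simulate_cohort(
    n_lines: int = 10,
    n_genes: int = 500,
    planted: int = 5,
    effect: float = 2.0,
    noise_sd: float = 0.05,
    activities: tuple[float, ...] = DEFAULT_ACTIVITIES,
    seed: int = 0,
) -> SimulatedCohort:
    """One coherent study: viability curves plus expression tied to true nAUC.

    Line plateaus are spread evenly over [0.1, 0.9] and rates over
    [0.2, 2.0] so the cohort spans sensitive to resistant; the expression
    phenotype is each line's closed-form true nAUC.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    plateaus = np.linspace(0.1, 0.9, n_lines)
    rates = np.linspace(2.0, 0.2, n_lines)
    params = [
        LinePhenotypeParams(
            line_id=f"LINE{i:02d}",
            plateau=float(plateaus[i]),
            rate=float(rates[i]),
            noise_sd=noise_sd,
        )
        for i in range(n_lines)
    ]
    viability, truth = simulate_viability(params, activities, seed=int(sub[0]))
    expression, expr_truth = simulate_expression(
        n_genes, truth, planted=planted, effect=effect, seed=int(sub[1])
    )
    labels = {
        line: ("resistant" if val >= float(np.median(list(truth.values()))) else "sensitive")
        for line, val in truth.items()
    }
    return SimulatedCohort(
        viability=viability,
        expression=expression,
        planted_genes=expr_truth["planted_genes"],
        true_nauc=truth,
        true_labels=labels,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plain-text I/O: tidy CSV, TSV matrix, GMT, JSON truth sidecar


def write_gmt(signature: dict[str, list[str]], path: str | Path) -> None:
    """Write class -> genes as GMT (name, description, tab-separated genes)."""
    with open(path, "w") as fh:
        for name, genes in signature.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file to class -> genes (line format: name, desc, genes...)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
            out[fields[0]] = [g for g in fields[2:] if g]
    return out


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Persist a cohort to plain-text files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "viability": outdir / "viability.csv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.viability.to_csv(paths["viability"], index=False)
    cohort.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    truth = {
        "planted_genes": sorted(cohort.planted_genes),
        "true_nauc": cohort.true_nauc,
        "true_labels": cohort.true_labels,
        "seed": cohort.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    if cohort.signature:
        paths["signature"] = outdir / "signature.gmt"
        write_gmt(cohort.signature, paths["signature"])
    return paths
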