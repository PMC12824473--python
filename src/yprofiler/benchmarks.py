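"""Self-contained evaluation runs used to validate the pipeline end to end.

Each function simulates a cohort with known ground truth, runs the relevant
pipeline stage, and returns summary metrics. They are used by the test suite
and by ``scripts/acceptance.py``; all randomness flows from the ``seed``
arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import ntp as ntp_mod
from . import stability, synthetic

__all__ = [
    "stability_recovery",
    "stability_null_calibration",
    "ntp_noiseless_accuracy",
    "ntp_null_uniformity",
]


def _standardized_cohort(seed: int, n_genes: int, planted: int, effect: float):
    cohort = synthetic.simulate_cohort(
        n_lines=10, n_genes=n_genes, planted=planted, effect=effect, seed=seed
    )
    std = stability.standardize_expression(
        ntp_mod.logcpm_transform(cohort.expression)
    )
    return cohort, std, pd.Series(cohort.true_nauc)


def stability_recovery(
    seeds: list[int],
    n_genes: int = 500,
    planted: int = 5,
    effect: float = 2.0,
    n_bootstrap: int = 100,
    threshold: float = 0.7,
) -> dict:
    """Mean recall/precision of planted-gene recovery over cohort seeds.

    Ten cell lines per cohort; recall = recovered planted / planted,
    precision = recovered planted / selected (1.0 when nothing selected,
    since no false positive was made).
    """
    recalls, precisions = [], []
    for seed in seeds:
        cohort, std, phen = _standardized_cohort(seed, n_genes, planted, effect)
        cfg = stability.ENConfig(n_bootstrap=n_bootstrap, seed=seed)
        table = stability.bootstrap_stability(std, phen, cfg)
        selected = set(stability.select_genes(table, threshold))
        tp = len(selected & cohort.planted_genes)
        recalls.append(tp / planted)
        precisions.append(tp / len(selected) if selected else 1.0)
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "per_seed_recall": recalls,
        "per_seed_precision": precisions,
    }


def stability_null_calibration(
    seed: int,
    n_genes: int = 500,
    n_bootstrap: int = 100,
    threshold: float = 0.7,
) -> dict:
    """Fraction of genes spuriously scored above threshold when the phenotype
    is shuffled independently of expression."""
    cohort, std, phen = _standardized_cohort(seed, n_genes, planted=5, effect=2.0)
    rng = np.random.default_rng(seed + 1)
    shuffled = pd.Series(rng.permutation(phen.to_numpy()), index=phen.index)
    cfg = stability.ENConfig(n_bootstrap=n_bootstrap, seed=seed + 2)
    table = stability.bootstrap_stability(std, shuffled, cfg)
    return {
        "fraction_selected": float((table["score"] >= threshold).mean()),
        "n_genes": int(len(table)),
    }


def ntp_noiseless_accuracy(seed: int, classes: int = 3, markers: int = 10) -> float:
    """Classification accuracy on noise-free signature profiles (expect 1.0)."""
    names = [f"C{i}" for i in range(classes)]
    profiles, sig_dict, labels = synthetic.simulate_signature_profiles(
        names, markers_per_class=markers, n_samples_per_class=4, noise_sd=0.0, seed=seed
    )
    templates = ntp_mod.build_templates(ntp_mod.SignatureSet.from_gmt_dict(sig_dict))
    calls = ntp_mod.ntp_classify(profiles, templates, n_perm=50, seed=seed)
    truth = pd.Series(labels)
    return float((calls["assigned_class"] == truth.loc[calls.index]).mean())


def ntp_null_uniformity(
    seed: int, n_samples: int = 200, markers: int = 10, n_perm: int = 200
) -> dict:
    """KS test of permutation p-values against Uniform(0,1) under pure noise.

    Profiles are i.i.d. Gaussian over a 2-class marker universe, so no class
    structure exists and p-values should be uniform.
    """
    sig_dict = {
        "A": [f"A_M{i}" for i in range(markers)],
        "B": [f"B_M{i}" for i in range(markers)],
    }
    templates = ntp_mod.build_templates(ntp_mod.SignatureSet.from_gmt_dict(sig_dict))
    rng = np.random.default_rng(seed)
    genes = list(templates.index)
    profiles = pd.DataFrame(
        rng.normal(size=(len(genes), n_samples)),
        index=genes,
        columns=[f"n{i}" for i in range(n_samples)],
    )
    calls = ntp_mod.ntp_classify(profiles, templates, n_perm=n_perm, seed=seed + 1)
    ks = stats.kstest(calls["p_value"].to_numpy(), "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_p_value": float(ks.pvalue)}
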