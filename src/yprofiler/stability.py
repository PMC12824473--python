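"""Bootstrap elastic-net stability selection.

Links baseline expression (log scale, standardized per gene) to a continuous
phenotype — here the per-line nAUC — by refitting an elastic net on bootstrap
resamples of the samples and scoring each gene by the consistency of its
coefficient *sign* across resamples:

    freq_pos = #(beta_g > 0) / B,  freq_neg = #(beta_g < 0) / B
    score    = max(freq_pos, freq_neg)

A gene is retained when its score reaches the threshold (default 0.7). The
max-of-sign-frequencies score is this package's reading of sign-frequency
stability scoring: it rewards genes selected with a consistent direction and
lives on the same 0-1 scale as the retention threshold. Genes that are
selected often but with alternating signs score low, as they should.

The elastic net objective (intercept unpenalized) is

    (1/2n) ||y - b0 - X beta||^2 + lam * (alpha ||beta||_1 + (1-alpha)/2 ||beta||_2^2)

which is exactly scikit-learn's ``ElasticNet(alpha=lam, l1_ratio=alpha)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV

__all__ = [
    "ENConfig",
    "standardize_expression",
    "fit_elastic_net",
    "bootstrap_stability",
    "select_genes",
    "gene_phenotype_correlation",
]


@dataclass(frozen=True)
class ENConfig:
    """Settings for bootstrap elastic-net stability selection.

    ``n_bootstrap`` resamples; ``mixing`` is the L1 fraction alpha in (0, 1];
    the penalty is chosen per resample by ``cv_folds``-fold inner
    cross-validation over a geometric grid of ``path_length`` values spanning
    ``path_eps`` (ratio of smallest to largest penalty), unless
    ``fixed_penalty`` is set, which bypasses the inner CV entirely.

    ``mixing`` defaults to 0.1 (ridge-dominant). Sign-frequency stability
    scoring needs the elastic net's grouping effect: biologically associated
    genes come in correlated clusters, and an L1-dominant penalty picks one
    arbitrary cluster member per resample, splitting the sign frequency
    across the cluster so that no member reaches the retention threshold. A
    ridge-dominant mixing co-selects the whole cluster with shared
    coefficients while the L1 part still zeroes unrelated genes.
    """

    n_bootstrap: int = 100
    mixing: float = 0.1
    path_length: int = 20
    path_eps: float = 1e-2
    cv_folds: int = 3
    fixed_penalty: float | None = None
    score_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.mixing <= 1.0:
            raise ValueError("mixing must be in (0, 1]")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")


def standardize_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene row to mean 0, SD 1 (sample SD, n-1).

    Zero-variance genes carry no association signal and break the scaling;
    they are dropped with a warning listing their identifiers.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize")
    values = matrix.to_numpy(float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    if not keep.all():
        dropped = list(matrix.index[~keep])
        warnings.warn(
            f"dropped {len(dropped)} zero-variance gene(s): {dropped[:10]}"
            + ("..." if len(dropped) > 10 else ""),
            stacklevel=2,
        )
    values = values[keep]
    centered = values - values.mean(axis=1, keepdims=True)
    scaled = centered / values.std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame(scaled, index=matrix.index[keep], columns=matrix.columns)


def fit_elastic_net(
    X: np.ndarray, y: np.ndarray, mixing: float = 0.5, penalty: float = 0.1
) -> tuple[np.ndarray, float]:
    """Fit one elastic net; returns (coefficients, intercept).

    ``X`` is samples x genes, ``y`` the phenotype vector; the intercept is
    unpenalized and X columns are used as-is (standardize first).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be samples x genes with rows matching y")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    model = ElasticNet(alpha=penalty, l1_ratio=mixing, max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def _resample_fit(X, y, config: ENConfig, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """One bootstrap resample + fit; redraws while y is degenerate.

    Returns (coefficient vector, number of degenerate redraws).
    """
    n = X.shape[0]
    redraws = 0
    while True:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if np.ptp(yb) > 0:
            break
        redraws += 1
        if redraws > 1000:
            raise RuntimeError("phenotype degenerate in 1000 consecutive resamples")
    Xb = X[idx]
    if config.fixed_penalty is not None:
        coef, _ = fit_elastic_net(Xb, yb, config.mixing, config.fixed_penalty)
        return coef, redraws
    cv = min(config.cv_folds, n)
    model = ElasticNetCV(
        l1_ratio=config.mixing,
        alphas=config.path_length,  # int: geometric grid of this many penalties
        eps=config.path_eps,
        cv=cv,
        max_iter=5_000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model.fit(Xb, yb)
    return model.coef_.copy(), redraws


def bootstrap_stability(
    expression: pd.DataFrame, phenotype: pd.Series, config: ENConfig | None = None
) -> pd.DataFrame:
    """Score every gene by coefficient-sign consistency over bootstrap fits.

    Parameters
    ----------
    expression
        Standardized genes x samples matrix (see
        :func:`standardize_expression`).
    phenotype
        One value per sample (e.g. mean nAUC), indexed like the expression
        columns.
    config
        :class:`ENConfig`; defaults used when omitted.

    Returns
    -------
    GeneScoreTable: one row per gene with ``freq_pos``, ``freq_neg``,
    ``score``, ``mean_coefficient`` (average over resamples), ``pearson_r``
    (on the full unresampled data), and ``selected``. The frame's ``attrs``
    carry ``n_degenerate_redraws`` as a resampling diagnostic.
    """
    config = config or ENConfig()
    common = [s for s in expression.columns if s in phenotype.index]
    if len(common) < 4:
        raise ValueError("need at least 4 samples shared by expression and phenotype")
    X = expression[common].to_numpy(float).T  # samples x genes
    y = phenotype.loc[common].to_numpy(float)
    rng = np.random.default_rng(config.seed)
    B = config.n_bootstrap
    n_genes = X.shape[1]
    pos = np.zeros(n_genes, dtype=int)
    neg = np.zeros(n_genes, dtype=int)
    coef_sum = np.zeros(n_genes)
    total_redraws = 0
    for _ in range(B):
        coef, redraws = _resample_fit(X, y, config, rng)
        total_redraws += redraws
        pos += coef > 0
        neg += coef < 0
        coef_sum += coef
    freq_pos = pos / B
    freq_neg = neg / B
    score = np.maximum(freq_pos, freq_neg)
    r = np.array([gene_phenotype_correlation(X[:, g], y) for g in range(n_genes)])
    table = pd.DataFrame(
        {
            "gene": expression.index,
            "freq_pos": freq_pos,
            "freq_neg": freq_neg,
            "score": score,
            "mean_coefficient": coef_sum / B,
            "pearson_r": r,
            "selected": score >= config.score_threshold,
        }
    ).set_index("gene")
    table.attrs["n_degenerate_redraws"] = total_redraws
    table.attrs["n_bootstrap"] = B
    return table


def select_genes(table: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Genes with score >= threshold, ordered by score desc, then
    |mean_coefficient| desc, then identifier."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    hits = table[table["score"] >= threshold]
    order = sorted(
        hits.index,
        key=lambda g: (-hits.at[g, "score"], -abs(hits.at[g, "mean_coefficient"]), g),
    )
    return order


def gene_phenotype_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between one gene's values and the phenotype."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one side of the correlation")
    return float(stats.pearsonr(x, y).statistic)
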