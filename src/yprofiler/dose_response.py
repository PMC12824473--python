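"""Dose-response phenotyping for radionuclide viability screens.

Turns raw per-replicate viability readouts measured over an activity ladder
(MBq/mL of :sup:`90`\\ Y microspheres) into normalized area-under-the-curve
(nAUC) phenotypes, assigns resistant / intermediate / sensitive group labels
from nAUC Z-scores, and provides the small set of physics utilities the assay
design rests on: radioactive decay, elapsed half-lives, and a MIRD-style
activity-concentration to absorbed-dose conversion.

Conventions
-----------
* nAUC = AUC of the normalized survival curve divided by the area of a flat
  100%-survival reference over the same activity span, so a fully resistant
  line scores 1 and a maximally sensitive one approaches 0.
* The AUC is integrated on the linear activity axis; the 100%-survival
  reference area is only well defined there.
* SEM uses the sample standard deviation (n-1 denominator).
* Z-scores across lines also use the sample SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DosePhysicsParams",
    "VIABILITY_COLUMNS",
    "normalize_viability",
    "trapezoid_auc",
    "nauc",
    "replicate_naucs",
    "summarize_nauc",
    "assign_groups",
    "compare_lines_anova",
    "mird_dose",
    "decay_activity",
    "half_lives_elapsed",
    "relative_expression",
    "ddct_log2fc",
]

#: Canonical column names of a tidy viability table.
VIABILITY_COLUMNS = ("cell_line", "replicate", "activity_mbq_per_ml", "readout")

#: MeV -> Joule.
_MEV_TO_J = 1.602176634e-13


@dataclass(frozen=True)
class DosePhysicsParams:
    """Physical constants of the radionuclide and absorbing medium.

    Defaults describe :sup:`90`\\ Y (beta emitter, 64.2 h half-life, mean beta
    energy 0.93 MeV per decay) suspended in unit-density aqueous medium.
    """

    half_life_hours: float = 64.2
    mean_energy_mev: float = 0.93
    medium_density_g_per_ml: float = 1.0

    def __post_init__(self) -> None:
        for name in ("half_life_hours", "mean_energy_mev", "medium_density_g_per_ml"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def _check_viability_columns(table: pd.DataFrame) -> None:
    missing = [c for c in VIABILITY_COLUMNS[:3] if c not in table.columns]
    if missing:
        raise ValueError(f"viability table missing columns: {missing}")


def normalize_viability(table: pd.DataFrame, readout_col: str = "readout") -> pd.DataFrame:
    """Convert raw readouts to surviving fractions relative to untreated control.

    Within each (cell_line, replicate) the readout at activity 0 is the
    untreated baseline; every readout is divided by it, so fraction(0) == 1
    exactly.

    Parameters
    ----------
    table
        Tidy frame with columns ``cell_line``, ``replicate``,
        ``activity_mbq_per_ml`` and the raw readout column.
    readout_col
        Name of the raw readout column (default ``"readout"``).

    Returns
    -------
    The same frame with a ``fraction`` column added (input is not mutated).

    Raises
    ------
    ValueError
        If any (line, replicate) lacks an activity-0 readout or its control
        readout is not strictly positive; the message names the offender.
    """
    _check_viability_columns(table)
    if readout_col not in table.columns:
        raise ValueError(f"viability table missing readout column {readout_col!r}")
    out = table.copy()
    fractions = np.empty(len(out), dtype=float)
    for (line, rep), idx in out.groupby(["cell_line", "replicate"]).groups.items():
        sub = out.loc[idx]
        ctrl = sub.loc[sub["activity_mbq_per_ml"] == 0, readout_col]
        if ctrl.empty:
            raise ValueError(f"no activity-0 control for line {line!r} replicate {rep}")
        ctrl_val = float(ctrl.iloc[0])
        if not ctrl_val > 0:
            raise ValueError(
                f"non-positive activity-0 control ({ctrl_val}) for line {line!r} replicate {rep}"
            )
        fractions[out.index.get_indexer(idx)] = sub[readout_col].to_numpy(float) / ctrl_val
    out["fraction"] = fractions
    return out


def trapezoid_auc(activities: np.ndarray, fractions: np.ndarray) -> float:
    """Trapezoidal area under a survival curve on the linear activity axis.

    Exact for piecewise-linear curves sampled at their knots.
    """
    a = np.asarray(activities, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need at least two (activity, fraction) points")
    if a.size != f.size:
        raise ValueError("activities and fractions differ in length")
    d = np.diff(a)
    if np.any(d <= 0):
        raise ValueError("activities must be strictly increasing (no duplicates)")
    return float(np.trapezoid(f, a))


def nauc(curve_auc: float, activity_span: float) -> float:
    """Normalize a curve AUC by the flat-100%-survival reference area.

    ``activity_span`` is A_max - A_min; the reference area is span x 1.0.
    Values slightly above 1 (replicate noise) are returned as-is — callers
    that need a flag should compare against 1 themselves; clamping would bias
    replicate statistics.
    """
    if not activity_span > 0:
        raise ValueError("activity span must be positive")
    return float(curve_auc) / float(activity_span)


def replicate_naucs(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-(line, replicate) nAUC from a normalized viability table.

    Integrates over the activities present in each replicate; warns when a
    replicate is missing the cohort's top activity, since that shrinks its
    reference span relative to the others.
    """
    _check_viability_columns(normalized)
    if "fraction" not in normalized.columns:
        raise ValueError("table has no 'fraction' column; run normalize_viability first")
    top = float(normalized["activity_mbq_per_ml"].max())
    rows = []
    for (line, rep), sub in normalized.groupby(["cell_line", "replicate"]):
        sub = sub.sort_values("activity_mbq_per_ml")
        acts = sub["activity_mbq_per_ml"].to_numpy(float)
        if acts.max() < top:
            warnings.warn(
                f"line {line!r} replicate {rep} missing top activity {top}; "
                "its nAUC span differs from the cohort's",
                stacklevel=2,
            )
        area = trapezoid_auc(acts, sub["fraction"].to_numpy(float))
        rows.append(
            {
                "cell_line": line,
                "replicate": rep,
                "nauc": nauc(area, acts.max() - acts.min()),
            }
        )
    return pd.DataFrame(rows)


def summarize_nauc(rep_naucs: pd.DataFrame) -> pd.DataFrame:
    """Per-line mean and SEM of replicate nAUC values.

    SEM = sample SD / sqrt(n); a single-replicate line gets SEM 0 with a
    warning, since no spread is estimable.
    """
    if rep_naucs.empty:
        raise ValueError("empty replicate nAUC table")
    rows = []
    for line, sub in rep_naucs.groupby("cell_line"):
        vals = sub["nauc"].to_numpy(float)
        n = vals.size
        if n == 1:
            warnings.warn(f"line {line!r} has a single replicate; SEM set to 0", stacklevel=2)
            sem = 0.0
        else:
            sem = float(np.std(vals, ddof=1) / math.sqrt(n))
        rows.append({"cell_line": line, "n": n, "mean_nauc": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows)


def assign_groups(
    profile: pd.DataFrame,
    resistant_z: float = 0.0,
    sensitive_z: float = -0.45,
) -> pd.DataFrame:
    """Label lines resistant / intermediate / sensitive by nAUC Z-score.

    Z-scores are computed across the per-line mean nAUCs with the sample SD.
    A line is resistant when z >= ``resistant_z`` and sensitive when
    z <= ``sensitive_z``; everything between is intermediate. The defaults
    (0 and -0.45) recover the canonical 5/3/2 split of the ten-line screen
    this pipeline was built around, but both are tuning knobs because group
    assignment in practice also weighs expression-space clustering.
    """
    if sensitive_z >= resistant_z:
        raise ValueError("sensitive_z must be below resistant_z")
    if "mean_nauc" not in profile.columns:
        raise ValueError("profile needs a 'mean_nauc' column (see summarize_nauc)")
    means = profile["mean_nauc"].to_numpy(float)
    if means.size < 2:
        raise ValueError("need at least two lines to compute Z-scores")
    sd = float(np.std(means, ddof=1))
    if sd == 0:
        raise ValueError("zero variance across line means; Z-scores undefined")
    out = profile.copy()
    out["z_score"] = (means - means.mean()) / sd
    out["group"] = np.select(
        [out["z_score"] >= resistant_z, out["z_score"] <= sensitive_z],
        ["resistant", "sensitive"],
        default="intermediate",
    )
    return out


def compare_lines_anova(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA across lines plus Tukey HSD pairwise comparisons.

    Parameters
    ----------
    groups
        Mapping line -> replicate nAUC values; every line needs >= 2
        replicates for the within-group variance to exist.

    Returns
    -------
    dict with keys ``f_statistic``, ``p_value`` and ``pairwise`` — a list of
    {line_a, line_b, mean_diff, p_adj} entries from the studentized-range
    (Tukey) adjustment.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two lines")
    arrays = []
    for name in names:
        v = np.asarray(groups[name], dtype=float)
        if v.size < 2:
            raise ValueError(f"line {name!r} has fewer than 2 replicates")
        arrays.append(v)
    if all(np.ptp(v) == 0 for v in arrays) and len({v[0] for v in arrays}) > 1:
        # zero within-group variance but distinct means: F is infinite
        f_stat, p_val = math.inf, 0.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        f_stat, p_val = float(f_stat), float(p_val)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise.append(
                {
                    "line_a": names[i],
                    "line_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(tukey.pvalue[i, j]),
                }
            )
    return {"f_statistic": f_stat, "p_value": p_val, "pairwise": pairwise}


def mird_dose(activity_mbq_per_ml: float, physics: DosePhysicsParams | None = None) -> float:
    """Absorbed dose (Gy) from an activity concentration, MIRD-style.

    Assumes complete decay of the administered activity, full local absorption
    of the mean beta energy, and a uniform medium, so the cumulated activity
    is A / lambda with lambda = ln 2 / T_half:

        D = (A / lambda) * E_mean / m

    With the :sup:`90`\\ Y defaults, 20 MBq/mL converts to ~993 Gy — the
    conventional "up to 1,000 Gy" top of the clinical in-vitro ladder.
    Linear in activity.
    """
    if activity_mbq_per_ml < 0:
        raise ValueError("activity concentration must be >= 0")
    p = physics or DosePhysicsParams()
    decay_const_per_s = math.log(2) / (p.half_life_hours * 3600.0)
    bq_per_g = activity_mbq_per_ml * 1e6 / p.medium_density_g_per_ml
    joules_per_g = (bq_per_g / decay_const_per_s) * p.mean_energy_mev * _MEV_TO_J
    return joules_per_g * 1000.0  # J/g -> J/kg = Gy


def decay_activity(a0: float, t_hours: float, half_life_hours: float = 64.2) -> float:
    """Activity remaining after ``t_hours`` of exponential decay."""
    if half_life_hours <= 0:
        raise ValueError("half-life must be positive")
    if t_hours < 0:
        raise ValueError("elapsed time must be >= 0")
    return a0 * 2.0 ** (-t_hours / half_life_hours)


def half_lives_elapsed(t_hours: float, half_life_hours: float = 64.2) -> float:
    """Number of half-lives in ``t_hours`` (e.g. a 240 h assay spans >3)."""
    if half_life_hours <= 0:
        raise ValueError("half-life must be positive")
    return t_hours / half_life_hours


def relative_expression(ct_target: float, ct_housekeeping: float) -> float:
    """qPCR relative expression 2^-(Ct_target - Ct_housekeeping)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_housekeeping)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_housekeeping)


def ddct_log2fc(dct_treated: float, dct_control: float) -> float:
    """Delta-delta-Ct log2 fold change: -(dCt_treated - dCt_control)."""
    if not (math.isfinite(dct_treated) and math.isfinite(dct_control)):
        raise ValueError("delta-Ct values must be finite")
    return -(dct_treated - dct_control)
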