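"""Pipeline orchestration: simulate -> nAUC -> group -> select -> classify -> DE.

A :class:`RunConfig` describes one reproducible run; :func:`run_pipeline`
executes the stages in dependency order, writes every artifact as TSV/JSON
with a ``#``-prefixed metadata header, and returns a manifest recording each
output's content hash, the seed, and per-stage sub-seeds.

Seeding: the single run seed is fanned out to per-stage sub-seeds through
``numpy.random.SeedSequence(seed).spawn``, hashed down to integers below
2^31, so any stage can be re-run in isolation with its recorded sub-seed and
reproduce its outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import dose_response as dr
from . import ntp as ntp_mod
from . import stability
from . import synthetic

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_config"]

log = logging.getLogger("yprofiler")

STAGES = ("simulate", "nauc", "select", "classify", "de")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    When ``viability_path`` / ``expression_path`` are unset the synthetic
    cohort generator supplies the inputs (sizes under ``synthetic``);
    otherwise files are loaded and validated. CLI flags override file values.
    """

    out_dir: str = "results"
    seed: int = 0
    viability_path: str | None = None
    expression_path: str | None = None
    signature_path: str | None = None
    activities: tuple[float, ...] = synthetic.DEFAULT_ACTIVITIES
    resistant_z: float = 0.0
    sensitive_z: float = -0.45
    n_bootstrap: int = 100
    en_mixing: float = 0.5
    score_threshold: float = 0.7
    n_perm: int = 1000
    de_q_max: float = 0.05
    de_lfc_min: float = 2.0
    only: tuple[str, ...] = STAGES
    synthetic: dict = field(
        default_factory=lambda: {"n_lines": 10, "n_genes": 500, "planted": 5, "effect": 2.0}
    )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML config file; keyword overrides win over file values."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def _write_table(df: pd.DataFrame, path: Path, meta: dict, index: bool = True) -> str:
    """Write TSV with '#'-prefixed metadata header lines; returns sha256."""
    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=index)
    text = buf.getvalue()
    path.write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()


def validate_inputs(config: RunConfig) -> dict[str, list[str]]:
    """Schema-check configured input files; returns {'errors': [...], 'warnings': [...]}.

    Checks: viability columns and per-replicate activity-0 presence;
    expression shape and sample overlap with viability lines; GMT
    well-formedness (errors cite line numbers).
    """
    errors: list[str] = []
    warnings_: list[str] = []
    via = None
    if config.viability_path:
        p = Path(config.viability_path)
        if not p.exists():
            errors.append(f"viability file not found: {p}")
        else:
            via = pd.read_csv(p)
            missing = [c for c in dr.VIABILITY_COLUMNS[:3] if c not in via.columns]
            if missing:
                errors.append(f"viability: missing columns {missing}")
            else:
                for (line, rep), sub in via.groupby(["cell_line", "replicate"]):
                    if not (sub["activity_mbq_per_ml"] == 0).any():
                        errors.append(f"viability: no activity-0 row for {line!r} rep {rep}")
    expr = None
    if config.expression_path:
        p = Path(config.expression_path)
        if not p.exists():
            errors.append(f"expression file not found: {p}")
        else:
            expr = pd.read_csv(p, sep="\t", index_col=0)
            if expr.shape[1] < 2:
                errors.append("expression: fewer than 2 samples")
    if via is not None and expr is not None and "cell_line" in via.columns:
        missing_lines = sorted(set(via["cell_line"]) - set(expr.columns))
        if missing_lines:
            errors.append(f"expression missing cell line(s) present in viability: {missing_lines}")
    if config.signature_path:
        p = Path(config.signature_path)
        if not p.exists():
            errors.append(f"signature file not found: {p}")
        else:
            try:
                sets = synthetic.read_gmt(p)
                if len(sets) < 2:
                    warnings_.append("signature: fewer than 2 classes; classification skipped")
            except ValueError as exc:
                errors.append(f"signature: {exc}")
    return {"errors": errors, "warnings": warnings_}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    The manifest records, per artifact, its path and sha256 content hash,
    plus the global seed, the per-stage sub-seeds, and the package version —
    enough to re-run any single stage in isolation.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    only = tuple(config.only)
    for stage in only:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; known: {STAGES}")
    report = validate_inputs(config)
    if report["errors"]:
        raise ValueError("input validation failed: " + "; ".join(report["errors"]))
    for w in report["warnings"]:
        log.warning(w)

    from importlib.metadata import version as pkg_version

    try:
        ver = pkg_version("yprofiler")
    except Exception:  # pragma: no cover - not installed
        ver = "unknown"
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "version": ver, "artifacts": {}}
    meta_base = {"seed": config.seed, "version": ver}

    def record(name: str, path: Path, digest: str) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": digest}

    # --- inputs: load or simulate -----------------------------------------
    cohort = None
    if config.viability_path:
        viability = pd.read_csv(config.viability_path)
        viability = dr.normalize_viability(viability)
        expression = (
            pd.read_csv(config.expression_path, sep="\t", index_col=0)
            if config.expression_path
            else None
        )
    else:
        log.info("stage simulate: generating synthetic cohort (seed %d)", seeds["simulate"])
        cohort = synthetic.simulate_cohort(
            activities=tuple(config.activities), seed=seeds["simulate"], **config.synthetic
        )
        viability = cohort.viability
        expression = cohort.expression
        if "simulate" in only:
            paths = synthetic.write_cohort(cohort, outdir / "synthetic")
            for name, p in paths.items():
                record(f"synthetic/{name}", p, hashlib.sha256(p.read_bytes()).hexdigest())

    # --- nAUC phenotyping --------------------------------------------------
    profile = None
    if "nauc" in only or {"select", "classify", "de"} & set(only):
        log.info("stage nauc: phenotyping %d lines", viability["cell_line"].nunique())
        reps = dr.replicate_naucs(viability)
        profile = dr.assign_groups(
            dr.summarize_nauc(reps), config.resistant_z, config.sensitive_z
        )
        if "nauc" in only:
            digest = _write_table(
                profile.set_index("cell_line"), outdir / "nauc_profile.tsv", meta_base
            )
            record("nauc_profile", outdir / "nauc_profile.tsv", digest)
            groups = {
                line: sub["nauc"].to_numpy() for line, sub in reps.groupby("cell_line")
            }
            if all(len(v) >= 2 for v in groups.values()):
                anova = dr.compare_lines_anova(groups)
                path = outdir / "anova.json"
                text = json.dumps(anova, indent=2)
                path.write_text(text)
                record("anova", path, hashlib.sha256(text.encode()).hexdigest())
            dose_rows = pd.DataFrame(
                {
                    "activity_mbq_per_ml": sorted(viability["activity_mbq_per_ml"].unique()),
                }
            )
            dose_rows["absorbed_dose_gy"] = [
                dr.mird_dose(a) for a in dose_rows["activity_mbq_per_ml"]
            ]
            digest = _write_table(dose_rows, outdir / "dose_table.tsv", meta_base, index=False)
            record("dose_table", outdir / "dose_table.tsv", digest)

    # --- stability selection ----------------------------------------------
    if "select" in only and expression is not None:
        log.info("stage select: bootstrap elastic net, B=%d", config.n_bootstrap)
        logcpm = ntp_mod.logcpm_transform(expression)
        std = stability.standardize_expression(logcpm)
        phen = profile.set_index("cell_line")["mean_nauc"]
        cfg = stability.ENConfig(
            n_bootstrap=config.n_bootstrap,
            mixing=config.en_mixing,
            score_threshold=config.score_threshold,
            seed=seeds["select"],
        )
        scores = stability.bootstrap_stability(std, phen, cfg)
        digest = _write_table(scores, outdir / "gene_scores.tsv", meta_base)
        record("gene_scores", outdir / "gene_scores.tsv", digest)
        hits = stability.select_genes(scores, config.score_threshold)
        path = outdir / "selected_genes.txt"
        text = "\n".join(hits) + "\n"
        path.write_text(text)
        record("selected_genes", path, hashlib.sha256(text.encode()).hexdigest())

    # --- template classification ------------------------------------------
    if "classify" in only and expression is not None and config.signature_path:
        log.info("stage classify: NTP with %d permutations", config.n_perm)
        sets = synthetic.read_gmt(config.signature_path)
        sig = ntp_mod.SignatureSet.from_gmt_dict(sets)
        templates = ntp_mod.build_templates(sig)
        logexpr = (
            ntp_mod.logcpm_transform(expression)
            if (expression.to_numpy() >= 0).all() and expression.to_numpy().max() > 50
            else expression
        )
        calls = ntp_mod.ntp_classify(
            logexpr, templates, n_perm=config.n_perm, seed=seeds["classify"]
        )
        digest = _write_table(calls, outdir / "subtype_calls.tsv", meta_base)
        record("subtype_calls", outdir / "subtype_calls.tsv", digest)
        if profile is not None:
            phen = profile.set_index("cell_line")["mean_nauc"]
            common = calls.index.intersection(phen.index)
            if len(common) and calls.loc[common, "assigned_class"].nunique() > 1:
                h, p = ntp_mod.subtype_phenotype_association(
                    calls.loc[common, "assigned_class"], phen
                )
                path = outdir / "subtype_association.json"
                text = json.dumps({"kruskal_h": h, "p_value": p}, indent=2)
                path.write_text(text)
                record("subtype_association", path, hashlib.sha256(text.encode()).hexdigest())

    # --- differential expression ------------------------------------------
    if "de" in only and expression is not None and profile is not None:
        grouping = profile.set_index("cell_line")["group"]
        two = grouping[grouping.isin(["resistant", "sensitive"])]
        counts = two.value_counts()
        if len(counts) == 2 and (counts >= 2).all():
            log.info("stage de: %s", dict(counts))
            logexpr = ntp_mod.logcpm_transform(expression[list(two.index)])
            table = de_mod.gene_wise_de(logexpr, two, group_a="sensitive", group_b="resistant")
            digest = _write_table(table, outdir / "de_results.tsv", meta_base)
            record("de_results", outdir / "de_results.tsv", digest)
            sig_table = de_mod.filter_significant(table, config.de_q_max, config.de_lfc_min)
            digest = _write_table(sig_table, outdir / "de_significant.tsv", meta_base)
            record("de_significant", outdir / "de_significant.tsv", digest)
        else:
            log.warning("stage de skipped: need >=2 resistant and >=2 sensitive lines")

    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return manifest
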