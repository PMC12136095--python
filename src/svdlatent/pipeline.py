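"""End-to-end pipeline: generate -> prepare -> correlate -> EFA -> score ->
associate -> SEM mediation -> site invariance -> report.

Each stage is a thin wrapper over the library modules; a run writes its
artifacts (CSV/JSON) plus a manifest recording inputs, seeds, package
version and output hashes.  A single global seed expands into per-stage
child seeds through a fixed counter scheme (``SeedSequence(seed).spawn``),
so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import fit_association
from .cognition import score_battery
from .cohort import (
    ALL_MARKERS,
    CohortConfig,
    generate_cohort,
    marker_kinds,
    prepare_markers,
)
from .correlations import mixed_matrix, kmo
from .efa import efa_pipeline
from .invariance import invariance_ladder
from .sem import (
    SVD_INDICATORS,
    bootstrap_bc_ci,
    decompose_effects,
    fit_ml,
    mediation_spec,
)

STAGES = ("generate", "efa", "score", "assoc", "sem", "invariance")


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 892
    out_dir: str = "results/run"
    stages: tuple = STAGES
    k_factors: int | str = "auto"
    prune_threshold: float = 0.2
    sem_exposures: tuple = ("age", "frs")
    n_boot: int = 500
    cohort: CohortConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _child_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _std(series: pd.Series) -> pd.Series:
    return (series - series.mean()) / series.std(ddof=0)


def sem_table(scored: pd.DataFrame, prepared: pd.DataFrame, exposure: str) -> pd.DataFrame:
    """Standardized observed-variable table for the mediation SEM."""
    out = pd.DataFrame(index=scored.index)
    for c in SVD_INDICATORS:
        out[c] = prepared[c]
    out["gm"] = _std(scored["gm_volume"])
    out["cognition"] = _std(scored["global_cognition"])
    out[exposure] = _std(scored[exposure])
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _child_seeds(config.seed, len(STAGES))))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_participants": config.n_participants,
        "stages": {},
        "warnings": [],
    }
    artifacts: dict = {}

    def record(stage, t0, files):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {f.name: _hash_file(f) for f in files},
        }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if "generate" in config.stages:
            t0 = time.time()
            cohort_cfg = config.cohort or CohortConfig()
            cohort_cfg = dataclasses.replace(
                cohort_cfg, n_participants=config.n_participants, seed=seeds["generate"]
            )
            table = generate_cohort(cohort_cfg)
            prepared, prep_record = prepare_markers(table)
            artifacts["table"] = table
            artifacts["prepared"] = prepared
            f1 = out_dir / "cohort.csv"
            table.to_csv(f1, index=False)
            f2 = out_dir / "cohort_config.yaml"
            cohort_cfg.to_yaml(f2)
            record("generate", t0, [f1, f2])

        if "efa" in config.stages:
            if "prepared" not in artifacts:
                raise RuntimeError("stage 'efa' needs the generate stage (no marker table)")
            t0 = time.time()
            sol = efa_pipeline(
                artifacts["prepared"], marker_kinds(),
                k=config.k_factors, prune_threshold=config.prune_threshold,
            )
            artifacts["efa"] = sol
            f1 = out_dir / "loadings.csv"
            sol.loadings.round(4).to_csv(f1)
            f2 = out_dir / "efa_summary.json"
            f2.write_text(json.dumps({
                "kmo": sol.kmo_overall,
                "rotation": sol.rotation,
                "max_interfactor_correlation": sol.rotation_info.get(
                    "max_interfactor_correlation"),
                "pruning_history": sol.pruning_history,
                "variance_explained": sol.variance_explained.round(4).to_dict(),
            }, indent=1))
            f3 = out_dir / "factor_scores.csv"
            sol.scores.round(5).to_csv(f3, index=False)
            record("efa", t0, [f1, f2, f3])

        if "score" in config.stages:
            t0 = time.time()
            scored = score_battery(artifacts["table"])
            if "efa" in artifacts:
                scores = artifacts["efa"].scores
                for c in scores.columns:
                    scored[f"score_{c}"] = scores[c].to_numpy()
            artifacts["scored"] = scored
            f1 = out_dir / "cohort_scored.csv"
            scored.to_csv(f1, index=False)
            record("score", t0, [f1])

        if "assoc" in config.stages:
            if "scored" not in artifacts or "efa" not in artifacts:
                raise RuntimeError("stage 'assoc' needs efa and score stages")
            t0 = time.time()
            rows = []
            outcomes = ["global_cognition"] + [
                c for c in artifacts["scored"].columns if c.startswith("domain_")]
            for outcome in outcomes:
                for factor in artifacts["efa"].scores.columns:
                    for level in (1, 2, 3):
                        res = fit_association(
                            artifacts["scored"], outcome, f"score_{factor}", level)
                        rows.append(res.as_dict())
            assoc = pd.DataFrame(rows)
            artifacts["assoc"] = assoc
            f1 = out_dir / "associations.csv"
            assoc.round(5).to_csv(f1, index=False)
            record("assoc", t0, [f1])

        if "sem" in config.stages:
            if "scored" not in artifacts:
                raise RuntimeError("stage 'sem' needs the score stage")
            t0 = time.time()
            sem_out = {}
            for exposure in config.sem_exposures:
                tab = sem_table(artifacts["scored"], artifacts["prepared"], exposure)
                spec = mediation_spec(x=exposure)
                fit = fit_ml(tab.cov(), len(tab), spec, seed=seeds["sem"])
                dec = decompose_effects(fit, exposure)

                def stat(df_, _spec=spec, _x=exposure):
                    f = fit_ml(df_.cov(), len(df_), _spec, seed=seeds["sem"])
                    d = decompose_effects(f, _x)
                    return {"direct": d.direct, "total_indirect": d.total_indirect,
                            "total": d.total, **d.pathways}

                cis = bootstrap_bc_ci(tab, stat, n_boot=config.n_boot,
                                      seed=seeds["sem"])
                sem_out[exposure] = {
                    "chi2": fit.chi2, "df": fit.df, "cfi": fit.cfi,
                    "rmsea": fit.rmsea, "srmr": fit.srmr,
                    "effects": {k: {"estimate": v[0], "ci_low": v[1], "ci_high": v[2]}
                                for k, v in cis.items()},
                    "proportion_mediated_pct": dec.proportion_mediated,
                }
            f1 = out_dir / "sem_mediation.json"
            f1.write_text(json.dumps(sem_out, indent=1, default=float))
            record("sem", t0, [f1])

        if "invariance" in config.stages:
            if "prepared" not in artifacts:
                raise RuntimeError("stage 'invariance' needs the generate stage")
            t0 = time.time()
            lad = invariance_ladder(artifacts["prepared"], "site",
                                    seed=seeds["invariance"])
            f1 = out_dir / "invariance.json"
            f1.write_text(json.dumps({
                "summary": lad.summary().round(5).to_dict(orient="index"),
                "comparisons": lad.comparisons.round(5).to_dict(orient="index"),
            }, indent=1))
            record("invariance", t0, [f1])

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    _write_report(out_dir, manifest, artifacts)
    return manifest


def _write_report(out_dir: Path, manifest: dict, artifacts: dict) -> None:
    lines = ["# svdlatent run report", "",
             f"seed: {manifest['seed']}, n: {manifest['n_participants']}", ""]
    if "efa" in artifacts:
        sol = artifacts["efa"]
        lines += ["## Factor structure", "",
                  f"KMO {sol.kmo_overall:.3f}; rotation {sol.rotation}; "
                  f"pruned {[v for v, _ in sol.pruning_history]}", "",
                  sol.loadings.round(2).to_markdown(), ""]
    if (out_dir / "sem_mediation.json").exists():
        lines += ["## Mediation", "",
                  (out_dir / "sem_mediation.json").read_text(), ""]
    if (out_dir / "invariance.json").exists():
        lines += ["## Site invariance", "",
                  (out_dir / "invariance.json").read_text(), ""]
    if manifest["warnings"]:
        lines += ["## Warnings", ""] + [f"- {w}" for w in manifest["warnings"]]
    (out_dir / "report.md").write_text("\n".join(lines))
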