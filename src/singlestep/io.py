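"""Run configuration (YAML) and report writers.

A run configuration collects file paths and the study knobs; unknown keys
are rejected so typos fail loudly. Report writers emit one
machine-readable JSON plus aggregate TSV tables shaped like the usual
variance-component / accuracy / ranking summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .experiment import EffortResult, EffortScenario, StudyConfig
from .mixedmodel import RemlOptions, VarianceEstimates

__all__ = ["RunConfig", "load_config", "write_report", "estimates_to_dict"]

_REML_KEYS = {"max_iter": int, "tol_loglik": float, "tol_params": float}
_TOP_KEYS = {
    "pedigree": str, "genotypes": str, "phenotypes": str, "out_dir": str,
    "efforts": list, "reps": int, "seed": int, "blend_weight": float,
    "scale_g": bool, "standardize": bool, "top_fraction": float,
    "group_stats": bool, "reml": dict,
}


@dataclass
class RunConfig:
    """Validated study configuration with defaults applied."""

    pedigree: str | None = None
    genotypes: str | None = None
    phenotypes: str | None = None
    out_dir: str = "results"
    efforts: tuple[int, ...] = (0, 25, 50, 75, 100)
    reps: int = 30
    seed: int = 0
    blend_weight: float = 0.95
    scale_g: bool = True
    standardize: bool = True
    top_fraction: float = 0.05
    group_stats: bool = True
    reml: RemlOptions = field(default_factory=RemlOptions)

    def validate(self) -> None:
        if not 0.0 < self.blend_weight <= 1.0:
            raise ValueError(f"blend_weight must be in (0, 1], got {self.blend_weight}")
        bad = [e for e in self.efforts if e not in (0, 25, 50, 75, 100)]
        if bad:
            raise ValueError(f"efforts must be among 0/25/50/75/100, got {bad}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")

    def scenarios(self) -> list[EffortScenario]:
        return [EffortScenario(e, self.reps) for e in self.efforts]

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            blend_weight=self.blend_weight, scale_g=self.scale_g,
            reml=self.reml, seed=self.seed, top_fraction=self.top_fraction,
            group_stats=self.group_stats, standardize=self.standardize,
        )


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration.

    An empty file yields all defaults (blend weight 0.95, 30 replicates,
    efforts 0/25/50/75/100). Unknown keys raise with the offending field
    path.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run configuration must be a YAML mapping")
    unknown = set(raw) - set(_TOP_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key, val in raw.items():
        if key == "reml":
            if not isinstance(val, dict):
                raise ValueError("reml: must be a mapping")
            bad = set(val) - set(_REML_KEYS)
            if bad:
                raise ValueError(f"unknown configuration key(s): "
                                 f"{sorted('reml.' + b for b in bad)}")
            kwargs["reml"] = RemlOptions(**{k: _REML_KEYS[k](v) for k, v in val.items()})
        elif key == "efforts":
            kwargs[key] = tuple(int(e) for e in val)
        else:
            caster = _TOP_KEYS[key]
            if caster is bool and not isinstance(val, bool):
                raise ValueError(f"configuration key {key!r}: expected true/false, got {val!r}")
            try:
                kwargs[key] = caster(val)
            except (TypeError, ValueError):
                raise ValueError(f"configuration key {key!r}: cannot interpret {val!r}") from None
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def estimates_to_dict(est: VarianceEstimates) -> dict:
    cs = est.structures
    return {
        "additive": cs.additive.tolist(),
        "block": None if cs.block is None else cs.block.tolist(),
        "residual": cs.residual.tolist(),
        "se": {k: float(v) for k, v in est.se.items()},
        "loglik": est.loglik,
        "aic": est.aic,
        "converged": est.converged,
        "n_iter": est.n_iter,
    }


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(results: Sequence[EffortResult], out_dir,
                 meta: dict | None = None) -> dict[str, Path]:
    """Write aggregate TSV tables and the full machine-readable JSON.

    ``variance_components.tsv`` mirrors the usual per-effort variance
    component/fit table, ``accuracy.tsv`` the per-class accuracies, and
    ``rankings.tsv`` the rank-agreement summaries; ``study.json`` holds
    every per-replicate number plus the metadata (seeds, versions).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows_vc, rows_acc, rows_rank = [], [], []
    for res in results:
        agg = res.aggregate()
        mean, sd = agg["mean"], agg["sd"]
        vc = {"effort": res.effort, "n_reps": len(res.replicates),
              "n_converged": res.n_converged}
        for col in mean.index:
            if col.startswith(("sigma2_", "h2_", "r_G", "aic", "loglik",
                               "pearson_r_with_A")):
                vc[col] = mean[col]
                vc[col + "_sd"] = sd[col]
        rows_vc.append(vc)

        for cls in ("maternal", "genotyped", "nongenotyped"):
            row = {"effort": res.effort, "class": cls}
            any_col = False
            for col in mean.index:
                if col.startswith(f"acc_{cls}_"):
                    trait = col[len(f"acc_{cls}_"):]
                    row[trait] = mean[col]
                    row[trait + "_sd"] = sd[col]
                    any_col = True
            if any_col:
                rows_acc.append(row)

        rk = {"effort": res.effort}
        for col in mean.index:
            if col.startswith(("spearman_", "top5_")):
                rk[col] = mean[col]
                rk[col + "_sd"] = sd[col]
        rows_rank.append(rk)

    for name, rows in (("variance_components", rows_vc),
                       ("accuracy", rows_acc), ("rankings", rows_rank)):
        p = out / f"{name}.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, na_rep="NA",
                                  float_format="%.6g")
        paths[name] = p

    payload = {
        "meta": meta or {},
        "efforts": [
            {
                "effort": res.effort,
                "rep_seeds": list(res.rep_seeds),
                "replicates": res.replicates.to_dict(orient="records"),
                "aggregate_mean": res.aggregate()["mean"].to_dict(),
                "aggregate_sd": res.aggregate()["sd"].to_dict(),
            }
            for res in results
        ],
    }
    p = out / "study.json"
    p.write_text(json.dumps(payload, indent=1, sort_keys=True,
                            default=_json_default, allow_nan=True) + "\n")
    paths["json"] = p
    return paths
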