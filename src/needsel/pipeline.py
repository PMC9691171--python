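"""End-to-end pipeline: code outcomes, build designs, fit, diagnose, AAP.

Driven by a YAML/dict config; every numeric default lives in the config and
every run writes a log with the seeds, draw counts and a hash of the model
spec, sufficient to reproduce the outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .design import ModelSpec, build_design, compute_vif, default_spec
from .effects import average_adjusted_probability, plot_barrier_aap, plot_needs_aap
from .io import read_panel, write_panel
from .model import SelectionMultinomialProbit, hosmer_lemeshow_refit
from .outcomes import derive_outcomes
from .synthetic import default_config, simulate_panel

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "input": None,            # path to a panel file, or None to simulate
    "simulate": {"n_individuals": 500, "n_waves": 5, "seed": 0},
    "spec": {},               # ModelSpec overrides (term lists, age_center)
    "fit": {"n_draws": 200, "seed": 0, "mode": "iid", "max_iter": 300},
    "aap": {"kind": "joint", "ages": None, "ci": True},
    "output_dir": "needsel-output",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = {k: dict(v) if isinstance(v, dict) else v
              for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if k not in merged:
            raise PipelineError("config", "unknown-key", f"unknown config key {k!r}")
        if isinstance(v, dict):
            merged[k].update(v)
        else:
            merged[k] = v
    if merged["spec"] is None or "eq2_terms" in merged["spec"] and not merged["spec"]["eq2_terms"]:
        raise PipelineError("config", "no-outcome-eq",
                            "the outcome-equation term list is empty")
    return merged


def run_pipeline(config) -> Path:
    """Run simulate/read -> code -> design -> fit -> diagnostics -> AAP.

    ``config`` is a mapping or a path to a YAML file; returns the artifact
    directory.  Any stage failure raises :class:`PipelineError` naming the
    stage.
    """
    cfg = _load_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    try:
        if cfg["input"]:
            panel = read_panel(cfg["input"])
        else:
            panel = simulate_panel(default_config(**cfg["simulate"]))
            write_panel(panel, out / "simulated_panel.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", "load-failed", str(exc)) from exc

    try:
        coded, excl = derive_outcomes(panel)
        coded.to_csv(out / "coded.csv", index=False)
        (out / "exclusions.txt").write_text(excl.to_text())
    except Exception as exc:
        raise PipelineError("code", "coding-failed", str(exc)) from exc

    try:
        spec = default_spec() if not cfg["spec"] else ModelSpec.from_dict(
            {**default_spec().to_dict(), **cfg["spec"]})
        design = build_design(coded, spec)
        vif1 = compute_vif(design.X1, design.eq1_names)
        vif2 = compute_vif(design.X2, design.eq2_names)
    except Exception as exc:
        raise PipelineError("design", "design-failed", str(exc)) from exc

    try:
        est = SelectionMultinomialProbit(spec=spec, **cfg["fit"])
        est.fit_design(design)
        fit = est.result_
        fit.summary_frame().to_csv(out / "estimates.csv", index=False)
        fit.params.to_text(out / "params.tsv", design.eq1_names, design.eq2_names)
    except Exception as exc:
        raise PipelineError("fit", "fit-failed", str(exc)) from exc

    try:
        hl_stat, hl_df, hl_p = hosmer_lemeshow_refit(design)
        diagnostics = {
            "max_vif_eq1": float(vif1.max()), "max_vif_eq2": float(vif2.max()),
            "hosmer_lemeshow": {"statistic": float(hl_stat), "df": int(hl_df),
                                "p_value": float(hl_p)},
            "aic": float(fit.aic), "bic": float(fit.bic),
            "loglik": float(fit.loglik), "converged": bool(fit.converged),
        }
        (out / "diagnostics.yaml").write_text(yaml.safe_dump(diagnostics))
    except Exception as exc:
        raise PipelineError("diagnostics", "diagnostics-failed", str(exc)) from exc

    try:
        aap_cfg = cfg["aap"]
        grid = average_adjusted_probability(
            fit, coded, kind=aap_cfg.get("kind", "joint"),
            ages=aap_cfg.get("ages"), ci=aap_cfg.get("ci", True))
        grid.to_csv(out / "aap.csv", index=False)
        import matplotlib
        matplotlib.use("Agg", force=False)
        plot_needs_aap(grid).savefig(out / "fig_needs_aap.png", dpi=120)
        plot_barrier_aap(grid).savefig(out / "fig_barrier_aap.png", dpi=120)
    except Exception as exc:
        raise PipelineError("aap", "aap-failed", str(exc)) from exc

    spec_hash = hashlib.sha256(
        json.dumps(spec.to_dict(), sort_keys=True).encode()).hexdigest()
    run_log = {
        "version": __version__,
        "numpy": np.__version__,
        "config": {k: v for k, v in cfg.items()},
        "spec_sha256": spec_hash,
        "fit": fit.metadata(),
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(run_log, sort_keys=False))
    return out
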