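"""End-to-end orchestration: simulate or load, preprocess, fit, report.

A run is described by a :class:`RunConfig` (usually loaded from YAML) and
produces a deterministic output directory: one JSON per fitted model, text
summary tables in both path-estimate and standardized-variance views, and a
provenance log recording package versions, the seed, and the resolved
configuration.  Re-running an identical config yields byte-identical fit
JSONs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from edutwin import __version__
from edutwin import preprocess as prep
from edutwin import twin_models as tm
from edutwin.synthetic import (
    ACEParams,
    CommonPathwayParams,
    SimplexComponent,
    SimplexParams,
    TwinPairTable,
    simulate_ace,
    simulate_common_pathway,
    simulate_simplex,
)

logger = logging.getLogger("edutwin")

KNOWN_MODELS = ("ace", "cholesky", "simplex", "cpm")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_csv`` (a wide twin CSV) or ``simulate`` (a block
    with ``model``, ``params``, ``n_mz``, ``n_dz``) must be given.
    """

    models: list[str]
    output_dir: str
    seed: int = 0
    input_csv: str | None = None
    simulate: dict | None = None
    measure: str = "ach"
    measures: list[str] | None = None
    ci_level: float = 0.95
    compute_ci: bool = False
    n_restarts: int = 10
    preprocess: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise ValueError("exactly one of input_csv or simulate must be set")
        unknown = [m for m in self.models if m not in KNOWN_MODELS]
        if unknown:
            raise ValueError(f"unknown models {unknown}; choose from {KNOWN_MODELS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _simplex_params_from_dict(d: dict) -> SimplexParams:
    comps = {}
    for key in ("a", "c", "e"):
        c = d[key]
        comps[key] = SimplexComponent(
            init_sd=float(c["init_sd"]),
            betas=tuple(c["betas"]),
            innov_sd=tuple(c["innov_sd"]),
            spec_sd=tuple(c["spec_sd"]),
        )
    return SimplexParams(**comps)


def build_params(model: str, params: dict):
    if model == "ace":
        return ACEParams(**params)
    if model == "simplex":
        return _simplex_params_from_dict(params)
    if model == "cpm":
        return CommonPathwayParams(
            latent_a=float(params["latent_a"]),
            latent_c=float(params["latent_c"]),
            latent_e=float(params["latent_e"]),
            loadings=tuple(params["loadings"]),
            resid_a2=tuple(params["resid_a2"]),
            resid_c2=tuple(params["resid_c2"]),
            resid_e2=tuple(params["resid_e2"]),
        )
    raise ValueError(f"cannot build generating parameters for model {model!r}")


def _simulate(config: RunConfig) -> TwinPairTable:
    block = dict(config.simulate)
    model = block.pop("model")
    n_mz = int(block.pop("n_mz"))
    n_dz = int(block.pop("n_dz"))
    params = build_params(model, block.pop("params"))
    sim = {"ace": simulate_ace, "simplex": simulate_simplex, "cpm": simulate_common_pathway}[model]
    return sim(n_mz, n_dz, params, seed=config.seed, measure=config.measure, **block)


def _fit_one(model: str, table: TwinPairTable, config: RunConfig) -> tm.FitResult:
    measures = config.measures
    kwargs = dict(n_restarts=config.n_restarts, seed=config.seed)
    if model == "ace":
        m = measures[0] if measures else f"{table.measure}1"
        return tm.fit_univariate_ace(table, m, **kwargs)
    if model == "cholesky":
        ms = measures or [f"{table.measure}1", f"{table.measure}2"]
        if len(ms) == 2:
            return tm.fit_bivariate_cholesky(table, ms, **kwargs)
        return tm.fit_cholesky(table, ms, **kwargs)
    if model == "simplex":
        return tm.fit_simplex(table, measures, **kwargs)
    if model == "cpm":
        return tm.fit_common_pathway(table, measures, **kwargs)
    raise ValueError(model)


def pct(x: float) -> str:
    """Whole-percent rendering used in the summary tables."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{round(100.0 * x):.0f}%"


def render_tables(fits: list[tm.FitResult]) -> dict[str, str]:
    """Text tables per fit: a path-estimate view and a standardized-variance
    view with whole-percent shares.  Returns {name: table text}."""
    out: dict[str, str] = {}
    if not fits:
        out["summary"] = "model\tquantity\tvalue\n"
        return out
    for fit in fits:
        lines = [f"# {fit.model} (-2lnL = {fit.neg2ll:.3f})"]
        lines.append("\n## Path estimates")
        for k, v in fit.estimates.items():
            ci = fit.ci.get(k)
            tail = f"  [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
            lines.append(f"{k}\t{v:.4f}{tail}")
        lines.append("\n## Standardized variance components")
        for key in ("a2", "c2", "e2"):
            if key in fit.derived:
                vals = np.atleast_1d(fit.derived[key])
                lines.append(key + "\t" + "\t".join(pct(v) for v in vals))
        for key in ("latent_a2", "latent_c2", "latent_e2"):
            if key in fit.derived:
                lines.append(key + "\t" + pct(fit.derived[key]))
        for key in ("transmitted_share", "innovation_share"):
            if key in fit.derived:
                vals = fit.derived[key]
                lines.append(key + "\t" + "\t".join(pct(v) for v in vals))
        for key in ("rG", "rC", "rE", "rPh", "share_a", "share_c", "share_e"):
            if key in fit.derived:
                v = fit.derived[key]
                txt = pct(v) if key.startswith("share") else (
                    "NA" if not np.isfinite(v) else f"{v:.3f}")
                lines.append(f"{key}\t{txt}")
        if fit.flags:
            lines.append("\n## Flags")
            lines.extend(fit.flags)
        out[fit.model] = "\n".join(lines) + "\n"
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> preprocess -> fit -> report.

    Returns a bundle dict with the fits and output paths; any stage failure
    raises with the stage name after persisting a partial log.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "setup"
    try:
        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            table = _simulate(config)
        else:
            table = TwinPairTable.from_csv(config.input_csv, measure=config.measure)
        logger.info("stage %s: %d pairs, %d occasions", stage, len(table.data), table.n_occasions)

        if config.preprocess:
            stage = "preprocess"
            table = prep.prepare_twin_table(table, seed=config.seed)
        table.to_csv(outdir / "phenotypes.csv")

        fits = []
        for model in config.models:
            stage = f"fit-{model}"
            fit = _fit_one(model, table, config)
            if config.compute_ci:
                for param in list(fit.estimates)[:3]:
                    tm.likelihood_ci(fit, param, config.ci_level)
            fits.append(fit)
            with open(outdir / f"fit_{fit.model}.json", "w") as fh:
                json.dump(fit.to_dict(), fh, indent=2, sort_keys=True)
            logger.info("stage %s: -2lnL = %.3f", stage, fit.neg2ll)

        stage = "report"
        tables = render_tables(fits)
        for name, text in tables.items():
            (outdir / f"table_{name}.txt").write_text(text)
        provenance = {
            "edutwin": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "models": config.models,
            "config": {k: v for k, v in vars(config).items()},
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True, default=str)
        )
        return {"fits": fits, "tables": tables, "output_dir": str(outdir)}
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
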