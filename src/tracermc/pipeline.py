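"""Experiment orchestration: configuration, execution, reporting.

An experiment is described by a YAML-serialisable :class:`ExperimentConfig`
(geometry, coefficient model, discretization, estimator settings, seed).
``run_experiment`` executes the full chain — surrogate geometry, embedding
box, CSF drive, chosen estimator — and writes a reproducible result bundle:
the resolved configuration (with hash), per-functional estimates as CSV,
allocation traces and rate fits as JSON.  ``report`` regenerates tables and
figures from a bundle alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import coefficients as co
from . import estimators as est
from . import transport
from .geometry import GeometrySpec, build_surrogate_hierarchy
from .problems import TransportSampler


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    model: str = "model2"
    method: str = "mlmc"  # mc | qmc | mlmc
    geometry: dict = field(default_factory=dict)
    diffusion: dict = field(default_factory=dict)
    model1: dict = field(default_factory=dict)
    model2: dict = field(default_factory=dict)
    boundary: dict = field(default_factory=dict)
    estimator: dict = field(default_factory=dict)
    tau_count: int = 48
    tau_spacing_minutes: float = 30.0
    dt_base_minutes: float = 15.0
    horizon_hours: float = 24.0
    box_refine_extra: int = 0
    seed: int = 0
    output_dir: str = "results"
    mesh_dir: str | None = None  # load a hierarchy instead of building one

    def __post_init__(self):
        if self.model not in ("model1", "model2"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.method not in ("mc", "qmc", "mlmc"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.mesh_dir is None and self.geometry is None:
            raise ConfigError("either a geometry spec or a mesh_dir is required")

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_sampler(cfg: ExperimentConfig) -> TransportSampler:
    if cfg.mesh_dir is not None:
        from .msh_io import read_hierarchy

        hierarchy = read_hierarchy(cfg.mesh_dir)
    else:
        spec = GeometrySpec(**cfg.geometry)
        hierarchy = build_surrogate_hierarchy(
            spec,
            seed=cfg.seed,
            dt_base=cfg.dt_base_minutes * 60.0,
            T=cfg.horizon_hours * 3600.0,
        )
    d = hierarchy.mesh(1).dim
    nu_default = 3.0 if d == 2 else 2.5
    diffusion = co.DiffusionParams(**{"nu": nu_default, **cfg.diffusion})
    model1 = co.Model1Params(**{"nu_v": nu_default, **cfg.model1}) if cfg.model1 or cfg.model == "model1" else None
    model2 = co.Model2Params(**cfg.model2) if cfg.model2 or cfg.model == "model2" else None
    boundary = transport.BoundaryParams(**cfg.boundary)
    tau = transport.default_tau_grid(cfg.tau_count, cfg.tau_spacing_minutes)
    return TransportSampler(
        hierarchy,
        model=cfg.model,
        diffusion=diffusion,
        model1=model1,
        model2=model2,
        boundary=boundary,
        tau=tau,
        box_refine_extra=cfg.box_refine_extra,
    )


def run_experiment(cfg: ExperimentConfig, sampler: TransportSampler | None = None) -> str:
    """Execute the configured estimator; returns the bundle directory."""
    out = os.path.join(cfg.output_dir, f"{cfg.model}_{cfg.method}_{cfg.config_hash()}")
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "config_resolved.yaml"), "w") as fh:
        yaml.safe_dump({**cfg.resolved(), "config_hash": cfg.config_hash()}, fh)

    stage = "geometry/fields/drive"
    try:
        sampler = sampler or build_sampler(cfg)
        stage = "estimation"
        econf = est.EstimatorConfig(seed=cfg.seed, **{"eps": 1e-2, **cfg.estimator})
        L = sampler.hierarchy.n_levels
        if cfg.method == "mc":
            result = est.mc_estimate(
                lambda rng: sampler.sample_qoi(L, rng), econf, level=L
            )
        elif cfg.method == "qmc":
            result = est.qmc_estimate(
                lambda u: sampler.sample_qoi_from_uniforms(L, u),
                sampler.qmc_dimension(L),
                econf,
                level=L,
            )
        else:
            result = est.mlmc_estimate(sampler.sample_pair, L, econf)
    except Exception as exc:  # annotate the failing stage for the user
        manifest = {"failed_stage": stage, "error": str(exc)}
        with open(os.path.join(out, "failure.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    names = sampler.functional_names()
    df = pd.DataFrame(
        {
            "functional": names,
            "estimate": result.estimate,
            "std_error": result.std_error,
        }
    )
    if cfg.method == "mlmc":
        df["sd"] = np.sqrt(est.telescoped_variance(list(result.info["stats"].values())))
    df.to_csv(os.path.join(out, "estimates.csv"), index=False)

    meta = {
        "method": result.method,
        "eps": result.eps,
        "theta": result.theta,
        "converged": bool(result.converged),
        "bias": result.bias,
        "worst_variance": result.variance,
        "total_cost": result.total_cost,
        "allocation": {str(k): (list(v) if isinstance(v, tuple) else int(v)) for k, v in result.allocation.items()},
        "seed": cfg.seed,
    }
    if cfg.method == "mlmc":
        stats = result.info["stats"]
        meta["levels"] = {
            str(l): {
                "n": s.n,
                "max_abs_mean_y": s.max_abs_mean_y,
                "max_var_y": s.max_var_y,
            }
            for l, s in stats.items()
        }
        rates = result.info.get("rates")
        if rates is not None:
            meta["rates"] = {"alpha": rates.alpha, "beta": rates.beta, "gamma": rates.gamma}
    with open(os.path.join(out, "result.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return out


def report(bundle_dir: str) -> list[str]:
    """Regenerate tables/figures from a result bundle; returns file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est_path = os.path.join(bundle_dir, "estimates.csv")
    if not os.path.exists(est_path):
        raise ConfigError(f"no estimates.csv in {bundle_dir}")
    df = pd.read_csv(est_path)
    if df.empty:
        raise ConfigError("empty functional set in bundle")
    with open(os.path.join(bundle_dir, "result.json")) as fh:
        meta = json.load(fh)

    outputs = []
    # mean (+/- SD when available) vs time, one panel per functional family
    fams = df["functional"].str.split("(").str[0]
    tau = df["functional"].str.extract(r"tau=(\d+)min")[0].astype(float)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, fam in zip(axes.ravel(), ["Q_g", "Q_w", "q_g", "q_w"]):
        sel = fams == fam
        t = tau[sel] / 60.0
        ax.plot(t, df.loc[sel, "estimate"], "-", color="tab:blue")
        if "sd" in df.columns:
            ax.errorbar(
                t, df.loc[sel, "estimate"], yerr=df.loc[sel, "sd"],
                fmt="none", ecolor="tab:blue", alpha=0.4,
            )
        ax.set_title(fam)
        ax.set_xlabel("time (h)")
    fig.tight_layout()
    path = os.path.join(bundle_dir, "functionals_vs_time.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    outputs.append(path)

    if "levels" in meta:
        levels = sorted(int(l) for l in meta["levels"])
        bias = [meta["levels"][str(l)]["max_abs_mean_y"] for l in levels]
        var = [meta["levels"][str(l)]["max_var_y"] for l in levels]
        fig, ax = plt.subplots(figsize=(6, 4.5))
        ax.semilogy(levels, bias, "o-", label="max |mean Y_l|", base=2)
        ax.semilogy(levels, var, "s-", label="max Var Y_l", base=2)
        if "rates" in meta:
            ax.set_title(
                "alpha-hat = %.2f, beta-hat = %.2f"
                % (meta["rates"]["alpha"], meta["rates"]["beta"])
            )
        ax.set_xlabel("level")
        ax.legend()
        fig.tight_layout()
        path = os.path.join(bundle_dir, "level_decay.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        outputs.append(path)
    return outputs
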