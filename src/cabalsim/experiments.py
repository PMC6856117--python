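"""Pre-registered experiment runners.

Each experiment regenerates the computational content of one headline figure
of the conflict analysis from its caption parameters, writing tidy CSV
tables plus a manifest (resolved configuration and its hash).  A ``scale``
factor shrinks replicate counts and horizons for desk-scale runs without
changing table schemas.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .abm import SimConfig, run_multilocus, run_single_locus_replicates
from .dynamics import (
    GenomeArchitecture,
    cycle_exact,
    distortion_k_theta_surface,
)
from .recursions import (
    introduce_suppressor,
    iterate_to_equilibrium,
    mean_distortion,
    step_single_locus,
    step_two_locus,
    time_to_purge,
)
from .trait_response import ConflictParams, TraitResponse, k_target

__all__ = [
    "ExperimentSpec",
    "run_experiment",
    "summarize_replicates",
    "EXPERIMENTS",
]


@dataclass
class ExperimentSpec:
    """Resolvable description of one experiment run."""

    experiment: str
    seed: int = 0
    scale: float = 1.0
    out_dir: Optional[str] = None
    overrides: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise KeyError(
                f"unknown experiment {self.experiment!r}; "
                f"known: {sorted(EXPERIMENTS)}"
            )
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def summarize_replicates(values) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n)) of replicate values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("standard error undefined for fewer than 2 replicates")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def _config_hash(cfg: Dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _equilibrium_distortion(tr, k, c_sup, *, p0=1e-6, eps_sup=1e-3, f=0.9):
    """Full pipeline: distorter from rarity, suppressor from rarity at
    distorter frequency f, two-locus iteration to equilibrium; returns the
    equilibrium mean individual distortion."""
    from .trait_response import distorter_invades

    if not distorter_invades(tr, k):
        return 0.0
    p = p0
    for _ in range(2_000_000):
        p = step_single_locus(p, tr, k)
        if p >= f:
            break
    params = ConflictParams(c_sup=c_sup, k=k)
    res = iterate_to_equilibrium(
        introduce_suppressor(p, eps_sup),
        lambda x: step_two_locus(x, tr, params),
        tol=1e-12,
        max_gen=5_000_000,
    )
    return mean_distortion(res.state, k)


# --- individual experiments -------------------------------------------------

_FIG1_TR = dict(a_t=0.87, b_t=1.0, a_c=0.9, b_c=1.5)
_FIG1_CSUP = 0.15
_FIG4_TR = dict(a_t=1.0, b_t=1.0, a_c=0.5, b_c=1.0)
_FIG4_CSUP = 0.1


def _exp_fig1a(spec: ExperimentSpec):
    cfg = {
        "tr": dict(_FIG1_TR),
        "c_sup": _FIG1_CSUP,
        "k_grid": list(np.round(np.linspace(0.05, 0.95, 19), 4)),
    }
    cfg.update(spec.overrides)
    tr = TraitResponse.power(**cfg["tr"])
    rows = [
        {
            "k": k,
            "equilibrium_distortion": _equilibrium_distortion(tr, k, cfg["c_sup"]),
        }
        for k in cfg["k_grid"]
    ]
    return {"fig1a_equilibrium_distortion": pd.DataFrame(rows)}, cfg


def _exp_fig1b(spec: ExperimentSpec):
    cfg = {
        "tr": dict(_FIG1_TR),
        "c_sup": _FIG1_CSUP,
        "k_grid": [0.35, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    }
    cfg.update(spec.overrides)
    tr = TraitResponse.power(**cfg["tr"])
    rows = []
    for k in cfg["k_grid"]:
        res = time_to_purge(tr, ConflictParams(c_sup=cfg["c_sup"], k=k))
        rows.append(
            {
                "k": k,
                "generations_to_purge": res.generations,
                "log10_generations": float(np.log10(res.generations)),
                "capped": res.capped,
            }
        )
    return {"fig1b_purge_time": pd.DataFrame(rows)}, cfg


def _exp_fig2a(spec: ExperimentSpec):
    cfg = {
        "tr": dict(a_t=1.0, b_t=1.0, a_c=0.5, b_c=1.0),
        "c_sup": 0.1,
        "N": 2000,
        "T_end": max(200, int(20_000 * spec.scale)),
        "n_replicates": max(1, int(round(20 * spec.scale))),
    }
    cfg.update(spec.overrides)
    tr = TraitResponse.power(**cfg["tr"])
    sim_cfg = SimConfig(
        N=cfg["N"],
        T_end=cfg["T_end"],
        seed=spec.seed,
        n_replicates=cfg["n_replicates"],
    )
    mean_k, mean_m, _ = run_single_locus_replicates(sim_cfg, tr, cfg["c_sup"])
    df = pd.DataFrame(
        {
            "generation": np.arange(1, mean_k.size + 1),
            "mean_Ek": mean_k,
            "mean_Em": mean_m,
        }
    )
    return {"fig2a_trajectory": df}, cfg


def _exp_fig2b(spec: ExperimentSpec):
    # Equilibrium distortion over (c_sup, k_target): the target strength is
    # swept through the curvature of the cost function, c_trait = a_c k^2.
    cfg = {
        "c_sup_grid": list(np.round(np.linspace(0.05, 0.6, 8), 4)),
        "a_c_grid": list(np.round(np.linspace(0.55, 1.0, 8), 4)),
        "delta": 0.01,
    }
    cfg.update(spec.overrides)
    rows = []
    for a_c in cfg["a_c_grid"]:
        tr = TraitResponse.power(1.0, 1.0, a_c, 2.0)
        kt = k_target(tr)
        for c_sup in cfg["c_sup_grid"]:
            eq = kt.k if tr.c(kt.k) <= c_sup else 0.0
            rows.append(
                {
                    "c_sup": c_sup,
                    "cost_curvature": a_c,
                    "k_target": kt.k,
                    "equilibrium_distortion": eq,
                }
            )
    return {"fig2b_heatmap": pd.DataFrame(rows)}, cfg


def _exp_fig4a(spec: ExperimentSpec):
    cfg = {
        "tr": dict(_FIG4_TR),
        "c_sup": _FIG4_CSUP,
        "k": 0.6,
        "theta": 0.5,
        "gamma": 1e6,
        "rho_D1": 1e-11,
        "rho_S1": 1e-11,
    }
    cfg.update(spec.overrides)
    tr = TraitResponse.power(**cfg["tr"])
    genome = GenomeArchitecture(
        gamma=cfg["gamma"],
        theta=cfg["theta"],
        rho_D1=cfg["rho_D1"],
        rho_S1=cfg["rho_S1"],
    )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        res = cycle_exact(genome, tr, ConflictParams(c_sup=cfg["c_sup"], k=cfg["k"]))
    df = pd.DataFrame(
        {
            "generation": np.arange(1, res.distortion.size + 1),
            "mean_distortion": res.distortion,
        }
    )
    summary = pd.DataFrame(
        [
            {
                "peak": res.peak,
                "trough": res.trough,
                "purge_generation": res.purge_generation,
                "evolutionary_average": res.evolutionary_average,
            }
        ]
    )
    return {"fig4a_timeseries": df, "fig4a_summary": summary}, cfg


def _exp_fig4b(spec: ExperimentSpec):
    cfg = {
        "tr": dict(_FIG4_TR),
        "c_sup": _FIG4_CSUP,
        "theta_grid": [0.1, 0.3, 0.5],
        "k_grid": list(np.round(np.linspace(0.05, 0.95, 19), 4)),
        "gamma": 1e6,
        "rho_D1": 1e-11,
        "rho_S1": 1e-11,
        "method": "exact" if spec.scale >= 1.0 else "approx",
    }
    cfg.update(spec.overrides)
    tr = TraitResponse.power(**cfg["tr"])
    genome = GenomeArchitecture(
        gamma=cfg["gamma"],
        theta=cfg["theta_grid"][0],
        rho_D1=cfg["rho_D1"],
        rho_S1=cfg["rho_S1"],
    )
    df = distortion_k_theta_surface(
        cfg["k_grid"], cfg["theta_grid"], genome, tr, cfg["c_sup"], method=cfg["method"]
    )
    return {"fig4b_surface": df}, cfg


def _exp_fig5(spec: ExperimentSpec, sophistication: str):
    rho_d = 4e-9 if sophistication == "low" else 2e-9
    cfg = {
        "tr": dict(a_t=1.0, b_t=1.0, a_c=0.5, b_c=1.0),
        "c_sup": 0.01,
        "k": 0.5,
        "rho_S1": 4e-9,
        "rho_D1": rho_d,
        "gamma_grid": [1e5, 1e6, 1e7],
        "theta_grid": [0.1, 0.5],
        "N": 2000,
        "T_end": max(200, int(30_000 * spec.scale)),
        "n_replicates": max(2, int(round(12 * spec.scale))),
    }
    cfg.update(spec.overrides)
    tr = TraitResponse.power(**cfg["tr"])
    rows = []
    for theta in cfg["theta_grid"]:
        for gamma in cfg["gamma_grid"]:
            genome = GenomeArchitecture(
                gamma=gamma, theta=theta, rho_D1=cfg["rho_D1"], rho_S1=cfg["rho_S1"]
            )
            sim_cfg = SimConfig(
                N=cfg["N"],
                T_end=cfg["T_end"],
                seed=spec.seed,
                k=cfg["k"],
                n_replicates=cfg["n_replicates"],
            )
            _, mean, se = run_multilocus(
                sim_cfg, genome, tr, cfg["c_sup"], mode="discrete",
                sophistication=sophistication,
            )
            rows.append(
                {
                    "theta": theta,
                    "gamma": gamma,
                    "sophistication": sophistication,
                    "mean_distortion": mean,
                    "standard_error": se,
                    "n_replicates": cfg["n_replicates"],
                }
            )
    return {f"fig5_{sophistication}_sophistication": pd.DataFrame(rows)}, cfg


EXPERIMENTS: Dict[str, Callable] = {
    "fig1a": _exp_fig1a,
    "fig1b": _exp_fig1b,
    "fig2a": _exp_fig2a,
    "fig2b": _exp_fig2b,
    "fig4a": _exp_fig4a,
    "fig4b": _exp_fig4b,
    "fig5a": lambda spec: _exp_fig5(spec, "low"),
    "fig5b": lambda spec: _exp_fig5(spec, "high"),
}


def run_experiment(spec: ExperimentSpec) -> Dict[str, pd.DataFrame]:
    """Run one experiment and (optionally) write its tables and manifest.

    Every output table carries the resolved-config hash; re-running with the
    same seed reproduces the tables exactly.
    """
    tables, resolved = EXPERIMENTS[spec.experiment](spec)
    resolved_full = {
        "experiment": spec.experiment,
        "seed": spec.seed,
        "scale": spec.scale,
        "package_version": __version__,
        **resolved,
    }
    h = _config_hash(resolved_full)
    for df in tables.values():
        df["config_hash"] = h
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = dict(resolved_full, config_hash=h)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return tables
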