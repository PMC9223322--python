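"""End-to-end orchestration: synth -> trace -> build -> detect -> risk -> metrics.

A run is fully described by a :class:`RunConfig`, which round-trips
losslessly through YAML.  Every stochastic stage derives its seed
deterministically from the master seed, so rerunning the same config
reproduces every artifact bit-exactly.  The calibration sweep maps the
coupling grid to global risk per model and labels the grid into
low/medium/high-risk terciles, standing in for dataset-specific coupling
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fixtures import DisarrayRegion, FixtureSpec, make_fixture
from .geometry import load_geometry, save_geometry
from .metrics import (
    MetricsConfig,
    ensemble_cluster_count,
    longitudinal_connection_fraction,
    occupied_voxel_fraction,
)
from .network import CouplingConfig, build_fibre_network
from .risk import ensemble_risk
from .substrate import DDMConfig
from .tractography import TractographyParams, generate_tract_set

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (raised before any work starts)."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Defaults follow the package-wide conventions: r = 7, cutoff = 2,
    d_sep = 0.7, node density 1/voxel, sigma = 5, r_tilde = 5, eps = 10,
    1000 sampled circuits; the ensemble size defaults to 50 networks per
    coupling value, a desk-scale setting (raise for production maps).
    """

    fixture: dict | None = None  # FixtureSpec kwargs
    geometry_path: str | None = None  # alternative to `fixture`
    model: str = "fibre"  # fibre | null | both
    c_values: list = dc_field(default_factory=lambda: [1.0])
    r: float = 7.0
    cutoff: float = 2.0
    tau: int = 20
    max_steps: int | None = None
    tract: dict = dc_field(default_factory=dict)  # TractographyParams overrides
    metrics: dict = dc_field(default_factory=dict)  # MetricsConfig overrides
    n_networks: int = 50
    n_circuits: int = 1000
    sigma: float = 5.0
    master_seed: int = 0
    outdir: str = "fibronet_run"

    def validate(self) -> None:
        if (self.fixture is None) == (self.geometry_path is None):
            raise ConfigError("exactly one of fixture / geometry_path is required")
        if self.model not in ("fibre", "null", "both"):
            raise ConfigError(f"unknown model {self.model!r}")
        if not self.c_values:
            raise ConfigError("c_values must contain at least one coupling value")
        if self.tau < 2:
            raise ConfigError("tau must be >= 2")
        if self.n_networks < 1:
            raise ConfigError("n_networks must be >= 1")

    # -- lossless YAML round trip -------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    # -- derived objects -----------------------------------------------
    def models(self) -> list[str]:
        return ["fibre", "null"] if self.model == "both" else [self.model]

    def tract_params(self, seed: int) -> TractographyParams:
        return TractographyParams(**{"seed": seed, **self.tract})

    def metrics_config(self) -> MetricsConfig:
        return MetricsConfig(**self.metrics)

    def ddm_config(self) -> DDMConfig:
        return DDMConfig(tau=self.tau, max_steps=self.max_steps)


def _stage_seed(master: int, *labels: str) -> int:
    """Deterministic 31-bit stage seed from the master seed and a label."""
    h = hashlib.sha256(("/".join(labels) + f"#{master}").encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_input(cfg: RunConfig):
    if cfg.fixture is not None:
        kwargs = dict(cfg.fixture)
        if "disarray" in kwargs:
            kwargs["disarray"] = [
                d if isinstance(d, DisarrayRegion) else DisarrayRegion(**d)
                for d in kwargs["disarray"]
            ]
        if "dims" in kwargs:
            kwargs["dims"] = tuple(kwargs["dims"])
        if "holes" in kwargs:
            kwargs["holes"] = [
                (tuple(c), float(r)) for c, r in kwargs["holes"]
            ]
        return make_fixture(FixtureSpec(**kwargs))
    return load_geometry(cfg.geometry_path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every requested stage; return the run manifest.

    The manifest records artifact paths with checksums, the global risk
    per (model, c), substrate and cluster counts, and the mean substrate
    OVF against the geometry-wide mean.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    geom, field = load_input(cfg)
    mcfg = cfg.metrics_config()
    ovf = occupied_voxel_fraction(geom, mcfg.r_tilde)
    geometry_mean_ovf = float(np.nanmean(ovf))

    geo_path = outdir / "geometry.npz"
    save_geometry(geo_path, geom, field)

    tracts = None
    artifacts = {"geometry": str(geo_path)}
    if "fibre" in cfg.models():
        if field is None:
            raise ConfigError("fibre model requires an orientation field")
        tp = cfg.tract_params(_stage_seed(cfg.master_seed, "trace"))
        tracts = generate_tract_set(
            geom, field, tp, np.random.default_rng(tp.seed)
        )
        tract_rows = [
            {
                "tract": i,
                "round": t.round_index,
                "n_points": len(t.points),
                "n_nodes": len(t.node_points),
                "arc_length": t.arc_length,
            }
            for i, t in enumerate(tracts.tracts)
        ]
        tract_path = outdir / "tracts.csv"
        pd.DataFrame(tract_rows).to_csv(tract_path, index=False)
        artifacts["tracts"] = str(tract_path)
        logger.info(
            "traced %d tracts, %d nodes (%.2f nodes/voxel)",
            len(tracts.tracts),
            tracts.n_nodes,
            tracts.n_nodes / geom.n_occupied,
        )

    results = []
    for model in cfg.models():
        for c in cfg.c_values:
            seed = _stage_seed(cfg.master_seed, "risk", model, f"{c:.6g}")
            coupling = CouplingConfig(c=float(c), r=cfg.r, cutoff=cfg.cutoff, seed=seed)
            rm = ensemble_risk(
                geom,
                field,
                model,
                coupling,
                cfg.ddm_config(),
                n_networks=cfg.n_networks,
                n_circuits_sampled=cfg.n_circuits,
                rng=np.random.default_rng(seed),
                tracts=tracts,
                sigma=cfg.sigma,
            )
            tag = f"{model}_c{c:.4g}"
            risk_path = outdir / f"risk_{tag}.npz"
            np.savez_compressed(
                risk_path,
                counts=rm.per_voxel_counts,
                local_risk=rm.local_risk,
                smoothed=rm.smoothed(),
                lambdas=rm.lambdas,
            )
            detected = rm.per_voxel_counts > 0
            substrate_mean_ovf = (
                float(np.nanmean(ovf[detected])) if detected.any() else None
            )
            cluster = None
            if detected.any():
                cc = ensemble_cluster_count(
                    rm.member_voxels,
                    mcfg,
                    np.random.default_rng(_stage_seed(cfg.master_seed, "cluster", tag)),
                )
                cluster = {
                    "n_clusters": cc.n_clusters,
                    "bootstrap_mean": cc.bootstrap_mean,
                    "interval": list(cc.interval),
                }
            results.append(
                {
                    "model": model,
                    "c": float(c),
                    "lambda": rm.lambda_,
                    "lambda_se": rm.lambda_se,
                    "mean_substrates": rm.mean_substrates,
                    "substrate_mean_ovf": substrate_mean_ovf,
                    "geometry_mean_ovf": geometry_mean_ovf,
                    "clusters": cluster,
                    "risk_artifact": str(risk_path),
                    "seed": seed,
                }
            )
            artifacts[f"risk_{tag}"] = str(risk_path)

    if tracts is not None and cfg.c_values:
        seed = _stage_seed(cfg.master_seed, "lcf")
        net = build_fibre_network(
            tracts,
            CouplingConfig(
                c=float(cfg.c_values[0]), r=cfg.r, cutoff=cfg.cutoff, seed=seed
            ),
        )
        lcf = longitudinal_connection_fraction(net, geom.shape)
        lcf_path = outdir / "lcf.npz"
        np.savez_compressed(lcf_path, lcf=lcf)
        artifacts["lcf"] = str(lcf_path)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "n_occupied_voxels": geom.n_occupied,
        "results": results,
        "artifacts": artifacts,
        "checksums": {k: _sha256(Path(v)) for k, v in artifacts.items()},
        "runtime_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def calibration_sweep(
    cfg: RunConfig, c_grid: dict | list | None = None
) -> pd.DataFrame:
    """Map the coupling grid to global risk per model.

    Runs a reduced ensemble at each (model, c), returning one row per
    combination with the ensemble-mean lambda, its standard error, mean
    substrate count and bootstrap-mean cluster count, and labels each
    model's grid into low/medium/high lambda terciles.
    """
    cfg.validate()
    if c_grid is None:
        c_grid = {m: list(cfg.c_values) for m in cfg.models()}
    elif not isinstance(c_grid, dict):
        c_grid = {m: list(c_grid) for m in cfg.models()}
    if any(len(v) < 2 for v in c_grid.values()):
        raise ConfigError("calibration sweep needs at least two c values")

    geom, field = load_input(cfg)
    mcfg = cfg.metrics_config()
    tracts = None
    if "fibre" in c_grid:
        tp = cfg.tract_params(_stage_seed(cfg.master_seed, "trace"))
        tracts = generate_tract_set(geom, field, tp, np.random.default_rng(tp.seed))

    rows = []
    for model, cs in c_grid.items():
        for c in cs:
            seed = _stage_seed(cfg.master_seed, "sweep", model, f"{c:.6g}")
            rm = ensemble_risk(
                geom,
                field,
                model,
                CouplingConfig(c=float(c), r=cfg.r, cutoff=cfg.cutoff, seed=seed),
                cfg.ddm_config(),
                n_networks=cfg.n_networks,
                n_circuits_sampled=cfg.n_circuits,
                rng=np.random.default_rng(seed),
                tracts=tracts,
                sigma=cfg.sigma,
            )
            detected = rm.per_voxel_counts > 0
            n_clusters = np.nan
            if detected.any():
                cc = ensemble_cluster_count(
                    rm.member_voxels,
                    mcfg,
                    np.random.default_rng(seed + 1),
                )
                n_clusters = cc.bootstrap_mean
            rows.append(
                {
                    "model": model,
                    "c": float(c),
                    "lambda": rm.lambda_,
                    "lambda_se": rm.lambda_se,
                    "mean_substrates": rm.mean_substrates,
                    "cluster_count": n_clusters,
                }
            )
    df = pd.DataFrame(rows)
    df["risk_label"] = ""
    for model in df["model"].unique():
        sel = df["model"] == model
        lam = df.loc[sel, "lambda"]
        terciles = lam.rank(pct=True)
        df.loc[sel, "risk_label"] = pd.cut(
            terciles, [0, 1 / 3, 2 / 3, 1.0001], labels=["low", "medium", "high"]
        ).astype(str)
    return df
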