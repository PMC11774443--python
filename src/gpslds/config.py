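"""Run configuration for the command-line experiment drivers.

A run is described by a single YAML/JSON document with three sections —
dataset, model, fit — plus an output directory.  The loaded configuration is
echoed (with all defaults filled in) into the output directory so a run can
be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    dataset: dict = field(default_factory=lambda: {
        "generator": "two_rotation",
        "params": {},
        "path": None,
    })
    model: dict = field(default_factory=lambda: {
        "K": 2, "J": 2, "n_inducing": 36, "kernel": "ssl",
        "feature_map": "affine", "temperature": 1.0, "process_noise": 0.1,
    })
    fit: dict = field(default_factory=lambda: {
        "dt_inference": 5e-3, "vem_iterations": 30, "n_init": 5, "seed": 0,
        "quad_order": 6, "m_step_maxiter": 8, "qx_sweeps": 1,
        "learn_sigma": True, "learn_obs": True,
    })
    analyze: dict = field(default_factory=lambda: {
        "grid_extent": 8.0, "grid_size": 25,
        "horizon_steps": 50, "spacing": 40,
    })
    output_dir: str = "gpslds_run"

    def to_fit_config(self, seed: int | None = None):
        from .inference import FitConfig

        m, f = self.model, self.fit
        return FitConfig(
            K=int(m.get("K", 2)),
            J=int(m.get("J", 2)),
            n_inducing=int(m.get("n_inducing", 36)),
            kernel_kind=m.get("kernel", "ssl"),
            feature_map_id=m.get("feature_map", "affine"),
            temperature=float(m.get("temperature", 1.0)),
            process_noise=float(m.get("process_noise", 0.1)),
            dt_inference=float(f.get("dt_inference", 5e-3)),
            vem_iterations=int(f.get("vem_iterations", 30)),
            n_init=int(f.get("n_init", 5)),
            seed=int(seed if seed is not None else f.get("seed", 0)),
            quad_order=int(f.get("quad_order", 6)),
            m_step_maxiter=int(f.get("m_step_maxiter", 8)),
            qx_sweeps=int(f.get("qx_sweeps", 1)),
            learn_sigma=bool(f.get("learn_sigma", True)),
            learn_obs=bool(f.get("learn_obs", True)),
        )

    def echo(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def load_run_config(path: str | Path | None) -> RunConfig:
    cfg = RunConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    for key, val in (doc or {}).items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown configuration section {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, dict) and isinstance(val, dict):
            current.update(val)
        else:
            setattr(cfg, key, val)
    return cfg
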