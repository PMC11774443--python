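"""HDF5 / JSON / CSV serialization.

Datasets are stored in an HDF5 container (schema version 1): one group per
trial with ragged event-time arrays or sampled traces, optional inputs, and a
metadata group recording how the dataset was generated so that ground truth
can be reconstructed deterministically.  Fit results store all arrays in HDF5
with the configuration echoed as JSON; ELBO traces export to CSV.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .inference import FitConfig, FitState, InducingPosterior, VariationalPath
from .kernels import RBFKernelParams, SSLKernelParams
from .simulate import GPSLDSModel, TrialData

SCHEMA_VERSION = 1

__all__ = ["save_dataset", "load_dataset", "save_fit_state", "load_fit_state",
           "elbo_trace_to_csv"]


def save_dataset(path, trials: list[TrialData], meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["n_trials"] = len(trials)
        f.attrs["kind"] = "point_process" if trials[0].is_point_process else "gaussian"
        if meta:
            f.attrs["meta"] = json.dumps(meta)
        for i, t in enumerate(trials):
            g = f.create_group(f"trials/trial_{i:04d}")
            g.attrs["duration"] = t.duration
            g.attrs["trial_id"] = t.trial_id
            if t.is_point_process:
                ev = g.create_group("events")
                for d, e in enumerate(t.events):
                    ev.create_dataset(f"ch_{d:04d}", data=e)
            else:
                g.create_dataset("sample_times", data=t.sample_times)
                g.create_dataset("observations", data=t.observations)
            if t.input_times is not None:
                g.create_dataset("input_times", data=t.input_times)
                g.create_dataset("input_values", data=t.input_values)


def load_dataset(path):
    """Returns ``(trials, meta)``; ``meta`` is the generator record, if any."""
    trials = []
    with h5py.File(path, "r") as f:
        if "trials" not in f:
            raise ValueError(f"{path}: not a dataset file (missing group 'trials')")
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else None
        for name in sorted(f["trials"]):
            g = f["trials"][name]
            kw = dict(duration=float(g.attrs["duration"]),
                      trial_id=int(g.attrs["trial_id"]))
            if "events" in g:
                ev = g["events"]
                kw["events"] = [ev[k][()] for k in sorted(ev)]
            else:
                kw["sample_times"] = g["sample_times"][()]
                kw["observations"] = g["observations"][()]
            if "input_times" in g:
                kw["input_times"] = g["input_times"][()]
                kw["input_values"] = g["input_values"][()]
            trials.append(TrialData(**kw))
    return trials, meta


def _kernel_to_json(kernel) -> str:
    return kernel.to_json()


def _kernel_from_json(doc: str):
    kind = json.loads(doc).get("kernel", "ssl")
    cls = SSLKernelParams if kind == "ssl" else RBFKernelParams
    return cls.from_json(doc)


def save_fit_state(path, state: FitState) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config"] = json.dumps(dataclasses.asdict(state.config))
        f.attrs["kernel"] = _kernel_to_json(state.model.kernel)
        f.attrs["link_id"] = state.model.link_id
        mg = f.create_group("model")
        mg.create_dataset("noise_cov", data=state.model.noise_cov)
        mg.create_dataset("obs_map", data=state.model.obs_map)
        mg.create_dataset("obs_offset", data=state.model.obs_offset)
        mg.create_dataset("inducing_locations", data=state.model.inducing_locations)
        if state.model.obs_noise_var is not None:
            mg.create_dataset("obs_noise_var", data=state.model.obs_noise_var)
        if state.model.input_map is not None:
            mg.create_dataset("input_map", data=state.model.input_map)
        qg = f.create_group("q_u")
        qg.create_dataset("mean", data=state.q_u.mean)
        qg.create_dataset("cov", data=state.q_u.cov)
        f.create_dataset("elbo_trace", data=np.asarray(state.elbo_trace))
        f.create_dataset("x0_prior_mean", data=state.x0_prior_mean)
        f.create_dataset("x0_prior_cov", data=state.x0_prior_cov)
        for i, p in enumerate(state.q_paths):
            pg = f.create_group(f"q_paths/trial_{i:04d}")
            for name in ("times", "weights", "marg_mean", "marg_cov",
                         "ctrl_lin", "ctrl_off", "init_mean", "init_cov"):
                pg.create_dataset(name, data=getattr(p, name))


def load_fit_state(path, trials: list[TrialData] | None = None) -> FitState:
    """Load a fit result; pass the trials to restore the observation grids."""
    from .likelihoods import build_grid_obs

    with h5py.File(path, "r") as f:
        cfg = FitConfig(**json.loads(f.attrs["config"]))
        mg = f["model"]
        model = GPSLDSModel(
            kernel=_kernel_from_json(f.attrs["kernel"]),
            noise_cov=mg["noise_cov"][()],
            obs_map=mg["obs_map"][()],
            obs_offset=mg["obs_offset"][()],
            link_id=str(f.attrs["link_id"]),
            obs_noise_var=mg["obs_noise_var"][()] if "obs_noise_var" in mg else None,
            input_map=mg["input_map"][()] if "input_map" in mg else None,
            inducing_locations=mg["inducing_locations"][()],
        )
        q_u = InducingPosterior(mean=f["q_u/mean"][()], cov=f["q_u/cov"][()])
        q_paths = []
        for name in sorted(f["q_paths"]):
            pg = f["q_paths"][name]
            q_paths.append(VariationalPath(**{k: pg[k][()] for k in pg}))
        state = FitState(
            model=model, q_paths=q_paths, q_u=q_u,
            elbo_trace=list(f["elbo_trace"][()]), config=cfg,
            x0_prior_mean=f["x0_prior_mean"][()], x0_prior_cov=f["x0_prior_cov"][()],
        )
    if trials is not None:
        state.grids = [build_grid_obs(t, cfg.dt_inference) for t in trials]
    return state


def elbo_trace_to_csv(path, trace) -> None:
    arr = np.asarray(trace, dtype=float)
    np.savetxt(path, np.column_stack([np.arange(len(arr)), arr]),
               delimiter=",", header="iteration,elbo", comments="")
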