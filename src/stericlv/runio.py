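"""HDF5 run bundles and CSV/JSON exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .config import RunConfig
from .dynamics import SimulationState, Trajectory
from .environment import StericEnvironment


def save_environment(env: StericEnvironment, path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("environment")
        _write_environment(g, env)


def _write_environment(g, env: StericEnvironment) -> None:
    g.create_dataset("centers", data=env.centers)
    g.create_dataset("valid_mask", data=env.valid_mask,
                     compression="gzip")
    g.attrs.update({
        "L": env.box_side, "R": env.pillar_radius,
        "dx": env.lattice_spacing, "delta": env.disorder,
        "pixels_per_lambda": env.pixels_per_lambda,
        "seed": -1 if env.seed is None else env.seed,
        "valid_area": env.valid_area,
    })


def _read_environment(g) -> StericEnvironment:
    seed = int(g.attrs["seed"])
    return StericEnvironment(
        box_side=float(g.attrs["L"]), pillar_radius=float(g.attrs["R"]),
        lattice_spacing=float(g.attrs["dx"]),
        disorder=float(g.attrs["delta"]), centers=g["centers"][()],
        pixels_per_lambda=float(g.attrs["pixels_per_lambda"]),
        seed=None if seed < 0 else seed,
        valid_mask=g["valid_mask"][()].astype(bool),
        valid_area=float(g.attrs["valid_area"]))


def load_environment(path) -> StericEnvironment:
    with h5py.File(path, "r") as fh:
        return _read_environment(fh["environment"])


def write_run_bundle(path, trajectory: Trajectory, env: StericEnvironment,
                     P: np.ndarray, config: RunConfig | None = None,
                     summary: dict | None = None,
                     store_fields: bool = True) -> None:
    """Write one run to a single HDF5 file: environment, interaction
    matrix, abundance series, final fields, and the summary JSON blob."""
    with h5py.File(path, "w") as fh:
        _write_environment(fh.create_group("environment"), env)
        fh.create_dataset("interaction_matrix", data=np.asarray(P))
        g = fh.create_group("trajectory")
        g.create_dataset("times", data=trajectory.times)
        g.create_dataset("mean_abundance", data=trajectory.mean_abundance)
        g.attrs["terminated_by"] = trajectory.terminated_by
        g.attrs["clamp_events"] = trajectory.clamp_events
        g.attrs["equilibrium_step"] = (
            -1 if trajectory.equilibrium_step is None
            else trajectory.equilibrium_step)
        if store_fields:
            fh.create_dataset("final_fields",
                              data=trajectory.final_state.fields,
                              compression="gzip")
            fh["final_fields"].attrs["time"] = trajectory.final_state.time
            fh["final_fields"].attrs["step_count"] = \
                trajectory.final_state.step_count
        if config is not None:
            fh.attrs["config_json"] = json.dumps(config.to_dict())
        if summary is not None:
            fh.attrs["summary_json"] = json.dumps(summary)


def read_run_bundle(path) -> dict:
    """Read a run bundle back; raises KeyError naming any absent dataset."""
    out: dict = {}
    with h5py.File(path, "r") as fh:
        out["environment"] = _read_environment(fh["environment"])
        out["interaction_matrix"] = fh["interaction_matrix"][()]
        g = fh["trajectory"]
        eq = int(g.attrs["equilibrium_step"])
        state = None
        if "final_fields" in fh:
            state = SimulationState(
                fields=fh["final_fields"][()],
                time=float(fh["final_fields"].attrs["time"]),
                step_count=int(fh["final_fields"].attrs["step_count"]))
        out["trajectory"] = Trajectory(
            times=g["times"][()], mean_abundance=g["mean_abundance"][()],
            terminated_by=str(g.attrs["terminated_by"]),
            final_state=state,
            clamp_events=int(g.attrs["clamp_events"]),
            equilibrium_step=None if eq < 0 else eq)
        if "config_json" in fh.attrs:
            out["config"] = RunConfig.from_dict(
                json.loads(fh.attrs["config_json"]))
        if "summary_json" in fh.attrs:
            out["summary"] = json.loads(fh.attrs["summary_json"])
    return out


def abundance_to_csv(trajectory: Trajectory, path) -> None:
    import pandas as pd

    n = trajectory.mean_abundance.shape[1]
    df = pd.DataFrame(trajectory.mean_abundance,
                      columns=[f"species_{i + 1}" for i in range(n)])
    df.insert(0, "time", trajectory.times)
    df.to_csv(path, index=False)


def matrix_to_csv(P: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(P), delimiter=",")


def centers_to_csv(env: StericEnvironment, path) -> None:
    np.savetxt(path, env.centers, delimiter=",", header="x,y", comments="")


def summary_to_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2))
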