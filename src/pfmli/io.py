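"""Run configuration, result serialization and run manifests."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams
from .protocols import (ProtocolSpec, SimulationResult, TrialSummary,
                        build_protocol, trial_table)

_KNOWN_KEYS = {"protocol", "n_repeats", "base_seed", "pf_rate", "w_hat_init",
               "overrides", "record_stride_ms", "outdir", "hdf5"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: a registered protocol plus overrides."""

    protocol: str = "I"
    n_repeats: Optional[int] = None
    base_seed: int = 7041
    pf_rate: Optional[float] = None
    w_hat_init: Optional[Union[str, float]] = None
    overrides: Dict[str, float] = field(default_factory=dict)
    outdir: str = "pfmli_out"
    hdf5: bool = False

    def to_spec(self) -> ProtocolSpec:
        params = ModelParams().with_overrides(self.overrides)
        return build_protocol(self.protocol, n_repeats=self.n_repeats,
                              base_seed=self.base_seed, pf_rate=self.pf_rate,
                              w_hat_init=self.w_hat_init, params=params)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An empty file yields all defaults (the published parameter values);
    unknown keys and out-of-range values raise a named error.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    data.pop("record_stride_ms", None)  # accepted but fixed at 1 ms currently
    cfg = RunConfig(**data)
    cfg.to_spec()  # validates protocol id, overrides and ranges eagerly
    return cfg


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    protocol: str
    base_seed: int
    n_repeats: int
    parameters: dict
    software_version: str
    wall_time_s: float
    outputs: List[str]
    python: str = field(default_factory=platform.python_version)

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _spikes_frame(result: SimulationResult) -> pd.DataFrame:
    """Two-column spike table; neuron_id -1 is the MLI, 0..n_pf-1 the fibers."""
    ids = [np.full(len(result.mli_spike_times), -1)]
    times = [result.mli_spike_times]
    for train in result.pf_spikes:
        ids.append(np.full(len(train.times), train.neuron_id))
        times.append(train.times)
    return pd.DataFrame({"neuron_id": np.concatenate(ids).astype(int),
                         "time_ms": np.concatenate(times)})


def _series_frame(result: SimulationResult) -> pd.DataFrame:
    df = pd.DataFrame({"t_ms": result.t_rec, "V_mV": result.V,
                       "mli_rate_hz": result.mli_rate_hz,
                       "mli_xbar": result.mli_xbar})
    for i in range(result.spec.n_pf):
        df[f"w_hat_{i}"] = result.w_hat[:, i]
        df[f"pf_xbar_{i}"] = result.pf_xbar[:, i]
    w0 = result.spec.params.synapse.w0
    df["mean_w_hat"] = result.w_hat.mean(axis=1)
    df["mean_w"] = w0 + (1 - w0) * df["mean_w_hat"]
    return df


def write_results(results: Sequence[SimulationResult],
                  summaries: Sequence[TrialSummary],
                  outdir: Union[str, Path], *, hdf5: bool = False,
                  wall_time_s: float = 0.0) -> RunManifest:
    """Write spikes, time series, trial summaries and a JSON manifest.

    Spikes and summaries are CSV; the stride-dense time series go to CSV
    by default or a single HDF5 file with ``hdf5=True``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = results[0].spec
    written: List[str] = []

    for res in results:
        p = outdir / f"spikes_rep{res.repeat_index}.csv"
        _spikes_frame(res).to_csv(p, index=False)
        written.append(p.name)

    if hdf5:
        import h5py
        p = outdir / "series.h5"
        with h5py.File(p, "w") as f:
            for res in results:
                g = f.create_group(f"rep{res.repeat_index}")
                df = _series_frame(res)
                for col in df.columns:
                    g.create_dataset(col, data=df[col].to_numpy(),
                                     compression="gzip")
        written.append(p.name)
    else:
        for res in results:
            p = outdir / f"series_rep{res.repeat_index}.csv"
            _series_frame(res).to_csv(p, index=False, float_format="%.6g")
            written.append(p.name)

    tidy = trial_table(results)
    p = outdir / "trial_summary.csv"
    tidy.to_csv(p, index=False)
    written.append(p.name)

    agg = pd.DataFrame([asdict(s) for s in summaries])
    p = outdir / "trial_summary_aggregate.csv"
    agg.to_csv(p, index=False)
    written.append(p.name)

    manifest = RunManifest(
        protocol=spec.id, base_seed=spec.base_seed, n_repeats=len(results),
        parameters={"neuron": asdict(spec.params.neuron),
                    "synapse": asdict(spec.params.synapse),
                    "mli_trace": asdict(spec.params.mli_trace),
                    "pf_trace": asdict(spec.params.pf_trace),
                    "plasticity": asdict(spec.params.plasticity),
                    "dt": spec.params.dt,
                    "w_hat_init": spec.w_hat_init
                    if isinstance(spec.w_hat_init, str)
                    else float(spec.w_hat_init)},
        software_version=__version__, wall_time_s=wall_time_s,
        outputs=sorted(written))
    manifest.write(outdir / "manifest.json")
    return manifest
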