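"""Delimited-text and JSON I/O for the pipeline's data products.

Train cohorts travel as long-format CSV (synapse_id, genotype,
f_stim_hz, stim_index, amplitude_pA), event streams as CSV with
time_s[, amplitude_pA], localizations as CSV with x_nm, y_nm, z_nm,
channel[, az_id], and model/protocol configuration as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .nanocluster import LocalizationCloud
from .quantal import DEFAULT_Q_STAR, MiniEventStream, QuantalTrain
from .simulator import CaTransientParams, PrimingModelParams, Protocol

TRAIN_COLUMNS = ["synapse_id", "genotype", "f_stim_hz", "stim_index",
                 "amplitude_pA"]


def write_train_table(trains: List[QuantalTrain], path) -> None:
    rows = []
    for t in trains:
        for j, a in enumerate(t.amplitudes, start=1):
            rows.append((t.synapse_id, t.genotype, t.f_stim, j, a))
    pd.DataFrame(rows, columns=TRAIN_COLUMNS).to_csv(path, index=False)


def read_train_table(path, q_star: float = DEFAULT_Q_STAR) -> List[QuantalTrain]:
    df = pd.read_csv(path)
    missing = set(TRAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"train table missing columns {sorted(missing)}")
    trains = []
    for (sid, geno, f), grp in df.groupby(
            ["synapse_id", "genotype", "f_stim_hz"], sort=True):
        grp = grp.sort_values("stim_index")
        trains.append(QuantalTrain(synapse_id=str(sid), f_stim=float(f),
                                   amplitudes=grp["amplitude_pA"].to_numpy(),
                                   genotype=str(geno), q_star=q_star))
    return trains


def write_event_stream(stream: MiniEventStream, path) -> None:
    data = {"time_s": stream.event_times}
    if stream.amplitudes is not None:
        data["amplitude_pA"] = stream.amplitudes
    pd.DataFrame(data).to_csv(path, index=False)


def read_event_stream(path, duration: float) -> MiniEventStream:
    df = pd.read_csv(path)
    amps = df["amplitude_pA"].to_numpy() if "amplitude_pA" in df.columns else None
    return MiniEventStream(event_times=df["time_s"].to_numpy(),
                           duration=duration, amplitudes=amps)


def write_localizations(clouds: List[LocalizationCloud], path) -> None:
    frames = []
    for c in clouds:
        df = pd.DataFrame(c.points, columns=["x_nm", "y_nm", "z_nm"])
        df["channel"] = c.channel
        if c.az_id is not None:
            df["az_id"] = c.az_id
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_localizations(path) -> Dict[str, LocalizationCloud]:
    df = pd.read_csv(path)
    out = {}
    for channel, grp in df.groupby("channel", sort=True):
        az = grp["az_id"].to_numpy() if "az_id" in grp.columns else None
        out[str(channel)] = LocalizationCloud(
            points=grp[["x_nm", "y_nm", "z_nm"]].to_numpy(),
            channel=str(channel), az_id=az)
    return out


def save_model_config(params: PrimingModelParams, ca_params: CaTransientParams,
                      path) -> None:
    cfg = {"model": dataclasses.asdict(params),
           "calcium": dataclasses.asdict(ca_params)}
    Path(path).write_text(json.dumps(cfg, indent=2))


def load_model_config(path) -> Tuple[PrimingModelParams, CaTransientParams]:
    cfg = json.loads(Path(path).read_text())
    return (PrimingModelParams(**cfg["model"]),
            CaTransientParams(**cfg["calcium"]))


def save_protocol(protocol: Protocol, path) -> None:
    Path(path).write_text(json.dumps({"ap_times": protocol.ap_times.tolist()}))


def load_protocol(path) -> Protocol:
    return Protocol(json.loads(Path(path).read_text())["ap_times"])


def save_ground_truth(truth: Dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float))


def load_ground_truth(path) -> Dict:
    return json.loads(Path(path).read_text())
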