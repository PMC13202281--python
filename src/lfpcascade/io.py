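"""Readers and writers for the package's on-disk formats.

LFP traces go out either as raw float32 with a one-line text sidecar
(fs / t0 / label) or as a two-column CSV (t, v); spikes and speed are
delimited tables. Analysis results are tidy delimited tables with metadata
header lines prefixed '#'. Tables are the contract; figures are a
convenience.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LfpChannel, SpeedTrace, SpikeTrain, SpikeTrainSet

__all__ = [
    "write_lfp_binary", "read_lfp_binary",
    "write_lfp_csv", "read_lfp_csv",
    "write_spikes", "read_spikes",
    "write_speed", "read_speed",
    "write_table", "read_table",
]


def write_lfp_binary(lfp: LfpChannel, path: str | Path) -> None:
    """Raw little-endian float32 samples plus a `.meta` text sidecar."""
    path = Path(path)
    lfp.samples.astype("<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    sidecar.write_text(
        f"fs={lfp.fs} t0={lfp.t0} label={lfp.label}\n")


def read_lfp_binary(path: str | Path) -> LfpChannel:
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta")
    for tok in sidecar.read_text().split():
        k, v = tok.split("=", 1)
        meta[k] = v
    samples = np.fromfile(path, dtype="<f4").astype(float)
    return LfpChannel(samples=samples, fs=float(meta["fs"]),
                      t0=float(meta.get("t0", 0.0)),
                      label=meta.get("label", "lfp"))


def write_lfp_csv(lfp: LfpChannel, path: str | Path) -> None:
    df = pd.DataFrame({"t": lfp.times, "v": lfp.samples})
    with open(path, "w") as fh:
        fh.write(f"# fs={lfp.fs} t0={lfp.t0} label={lfp.label}\n")
        df.to_csv(fh, index=False)


def read_lfp_csv(path: str | Path) -> LfpChannel:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    return LfpChannel(samples=df["v"].to_numpy(),
                      fs=float(meta.get("fs") or
                               1.0 / np.median(np.diff(df["t"]))),
                      t0=float(meta.get("t0", df["t"].iloc[0])),
                      label=meta.get("label", "lfp"))


def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        {"unit_id": u.unit_id, "region": u.region,
         "cell_type": u.cell_type, "time_s": t}
        for u in spikes for t in u.times
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "region", "cell_type",
                                     "time_s"])
    with open(path, "w") as fh:
        fh.write(f"# duration={spikes.duration} t0={spikes.t0}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_spikes(path: str | Path) -> SpikeTrainSet:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    units = []
    for uid, g in df.groupby("unit_id", sort=True):
        units.append(SpikeTrain(
            unit_id=str(uid), times=np.sort(g["time_s"].to_numpy()),
            region=str(g["region"].iloc[0]),
            cell_type=str(g["cell_type"].iloc[0])))
    duration = float(meta.get("duration") or df["time_s"].max())
    return SpikeTrainSet(units=units, duration=duration,
                         t0=float(meta.get("t0", 0.0)))


def write_speed(speed: SpeedTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": speed.t, "speed_cm_s": speed.v})
    with open(path, "w") as fh:
        fh.write(f"# fs_speed={speed.fs_speed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_speed(path: str | Path) -> SpeedTrace:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    t = df["time_s"].to_numpy()
    fs = float(meta.get("fs_speed") or 1.0 / np.median(np.diff(t)))
    return SpeedTrace(t=t, v=df["speed_cm_s"].to_numpy(), fs_speed=fs)


def write_table(df: pd.DataFrame, path: str | Path,
                meta: dict | None = None) -> None:
    """Tidy delimited table with '#'-prefixed key=value metadata lines."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            if isinstance(v, (dict, list, tuple)):
                v = json.dumps(v)
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta = _read_meta(path, strip_space=True)
    df = pd.read_csv(path, sep="\t", comment="#")
    return df, meta


def _read_meta(path: str | Path, strip_space: bool = False) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            for tok in (body.split(" ") if not strip_space else [body]):
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k.strip()] = v.strip()
    return meta
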