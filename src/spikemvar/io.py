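"""File formats: spike CSV, model JSON, report JSON.

Spike trains travel as a two-column CSV (``channel,time_s``), one row per
spike, times in seconds at microsecond precision; channels are sorted by
label for a deterministic ordering.  Models serialize as JSON in propagation
form (``x(n) = sum_k B(k) x(n-k) + w``), which is how the generative
examples are written.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lnp_simulator import LNPModel, SpikeTrainSet
from .mvar_core import MVARModel
from .nonlinearity import NonlinearitySpec

__all__ = [
    "read_spikes",
    "write_spikes",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    """Write a spike-train set as ``channel,time_s`` CSV (6 decimal places)."""
    rows = []
    for ch, train in enumerate(spikes.trains):
        rows.append(
            pd.DataFrame({"channel": np.full(train.size, ch + 1), "time_s": train})
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["channel", "time_s"])
    )
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    sidecar.write_text(
        json.dumps({"duration": spikes.duration, "bin_width": spikes.bin_width})
    )


def read_spikes(
    path: str | Path,
    *,
    duration: float | None = None,
    bin_width: float | None = None,
) -> SpikeTrainSet:
    """Read a ``channel,time_s`` CSV into a spike-train set.

    Channel labels are sorted for deterministic ordering.  Duration comes
    from the sidecar JSON written by :func:`write_spikes`, an explicit
    argument, or (as a fallback) the maximum spike time.  Unsorted times are
    sorted with a warning; negative times are an error.
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["channel", "time_s"]:
        raise ValueError(
            f"{path}: expected header 'channel,time_s', got {list(df.columns)}"
        )
    bad = df["time_s"].isna() | pd.to_numeric(df["time_s"], errors="coerce").isna()
    if bad.any():
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")
    if (df["time_s"] < 0).any():
        line = int((df["time_s"] < 0).idxmax()) + 2
        raise ValueError(f"{path}: negative spike time at line {line}")
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if duration is None:
        duration = meta.get("duration")
    if bin_width is None:
        bin_width = meta.get("bin_width", 1e-3)
    trains = []
    for _, group in sorted(df.groupby("channel"), key=lambda kv: kv[0]):
        t = group["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            import warnings

            warnings.warn(f"{path}: unsorted spike times; sorting", RuntimeWarning)
            t = np.sort(t)
        trains.append(t)
    if duration is None:
        duration = max((t[-1] for t in trains if t.size), default=0.0) + 1e-6
    return SpikeTrainSet(tuple(trains), duration=float(duration),
                         bin_width=float(bin_width))


def model_to_dict(model: LNPModel | MVARModel) -> dict:
    """JSON-ready dict; MVAR coefficients in propagation form."""
    mvar = model.mvar if isinstance(model, LNPModel) else model
    out = {
        "p": mvar.p,
        "m": mvar.m,
        "propagation": mvar.propagation.tolist(),
        "sigma": mvar.Sigma.tolist(),
    }
    if isinstance(model, LNPModel):
        out["nonlinearity"] = {
            "kind": model.nl.kind,
            "mu": model.nl.mu.tolist(),
            "sigma": model.nl.sigma.tolist(),
        }
        out["bin_width"] = model.bin_width
    return out


def model_from_dict(d: dict) -> LNPModel | MVARModel:
    mvar = MVARModel.from_propagation(
        np.asarray(d["propagation"], dtype=float), np.asarray(d["sigma"], dtype=float)
    )
    if "nonlinearity" not in d:
        return mvar
    nl = d["nonlinearity"]
    return LNPModel(
        mvar=mvar,
        nl=NonlinearitySpec(nl["kind"], np.asarray(nl["mu"]), np.asarray(nl["sigma"])),
        bin_width=float(d.get("bin_width", 1e-3)),
    )


def save_model(model: LNPModel | MVARModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def load_model(path: str | Path) -> LNPModel | MVARModel:
    return model_from_dict(json.loads(Path(path).read_text()))
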