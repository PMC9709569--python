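"""Readers and writers for epoched data and fitted models.

Two container formats, both self-describing and versioned:

* ``EpochContainer`` — a directory with ``header.json`` (version,
  timestep, flags, channel labels), ``meta.csv`` (one row per trial) and
  either per-trial ``trial_XXXX.csv`` matrices (text mode, round-trips to
  ~1e-16 relative precision via repr-precision floats) or a single
  ``trials.npz`` (binary mode, bit-exact round-trip).
* ``ModelArchive`` — one ``.npz`` with the parameter matrices and a JSON
  metadata string (rank, penalty, dropped channel, version, seed).

Loading refuses archives written by a newer major format version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochedData
from .vecm import VECMParams

__all__ = ["read_epochs", "write_epochs", "read_model", "write_model"]

FORMAT_VERSION = "1.0"


def _check_version(version: str, what: str) -> None:
    major = int(str(version).split(".")[0])
    if major > int(FORMAT_VERSION.split(".")[0]):
        raise ValueError(
            f"{what} was written by format version {version}; "
            f"this build reads up to major version {FORMAT_VERSION.split('.')[0]}"
        )


def write_epochs(data: EpochedData, path: str | Path, mode: str = "binary") -> Path:
    """Write an epoch container directory; ``mode`` is 'binary' or 'csv'."""
    if mode not in ("binary", "csv"):
        raise ValueError("mode must be 'binary' or 'csv'")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "format_version": FORMAT_VERSION,
        "kind": "epoch-container",
        "mode": mode,
        "delta": data.delta,
        "channel_labels": list(data.channel_labels),
        "common_average": data.common_average,
        "dropped_channel": data.dropped_channel,
        "n_trials": data.n_trials,
    }
    (path / "header.json").write_text(json.dumps(header, indent=2))
    if data.trial_meta is not None:
        data.trial_meta.to_csv(path / "meta.csv", index=False)
    if mode == "binary":
        arrays = {f"trial_{m:04d}": t for m, t in enumerate(data.values)}
        np.savez(path / "trials.npz", **arrays)
    else:
        for m, t in enumerate(data.values):
            np.savetxt(
                path / f"trial_{m:04d}.csv",
                t,
                delimiter=",",
                fmt="%.17g",
                header=",".join(data.channel_labels),
                comments="",
            )
    return path


def read_epochs(path: str | Path) -> EpochedData:
    """Read an epoch container written by :func:`write_epochs`."""
    path = Path(path)
    header = json.loads((path / "header.json").read_text())
    _check_version(header["format_version"], "epoch container")
    labels = header["channel_labels"]
    meta = None
    if (path / "meta.csv").exists():
        meta = pd.read_csv(path / "meta.csv")
    if header["mode"] == "binary":
        with np.load(path / "trials.npz") as z:
            values = [z[f"trial_{m:04d}"] for m in range(header["n_trials"])]
    else:
        values = []
        for m in range(header["n_trials"]):
            f = path / f"trial_{m:04d}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing trial file {f}")
            t = np.loadtxt(f, delimiter=",", skiprows=1, ndmin=2)
            if t.shape[1] != len(labels):
                raise ValueError(
                    f"trial file {f.name} has {t.shape[1]} columns, "
                    f"expected {len(labels)} channels"
                )
            values.append(t)
    data = EpochedData(
        values,
        labels,
        float(header["delta"]),
        meta,
        common_average=bool(header.get("common_average", False)),
        dropped_channel=header.get("dropped_channel"),
    )
    return data


def write_model(fit: VECMParams, path: str | Path, provenance: dict | None = None) -> Path:
    """Serialize a fitted model plus provenance to one .npz archive."""
    path = Path(path)
    info = dict(fit.info)
    info.pop("eigenvalues", None)
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": "vecm-model",
        "rank": fit.rank,
        "info": info,
        "provenance": provenance or {},
    }
    eigenvalues = fit.info.get("eigenvalues")
    arrays = {
        "mu": fit.mu,
        "alpha": fit.alpha,
        "beta": fit.beta,
        "Sigma": fit.Sigma,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if eigenvalues is not None:
        arrays["eigenvalues"] = np.asarray(eigenvalues)
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_model(path: str | Path) -> VECMParams:
    """Load a model archive written by :func:`write_model`."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        _check_version(meta["format_version"], "model archive")
        info = meta.get("info", {})
        if "eigenvalues" in z:
            info["eigenvalues"] = z["eigenvalues"]
        info["provenance"] = meta.get("provenance", {})
        return VECMParams(
            mu=z["mu"],
            alpha=z["alpha"],
            beta=z["beta"],
            Sigma=z["Sigma"],
            rank=int(meta["rank"]),
            info=info,
        )
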