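"""Plain-text readers and writers for recordings and connectivity matrices.

Recordings travel as a tab-separated channels x samples matrix plus a JSON
sidecar ``{labels, sampling_rate_hz, stage}``; connectivity matrices as TSV
with a header row and label column plus a sidecar ``{stage, band,
normalized, mi_units}``. EDF reading is supported when ``mne`` is
installed. Floats are written with a fixed format so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .preprocess import Recording

FLOAT_FMT = "%.12g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> list[Path]:
    """Write a recording as TSV + JSON sidecar; returns the written paths."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.data, delimiter="\t", fmt=FLOAT_FMT)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "labels": list(rec.labels),
        "sampling_rate_hz": rec.sampling_rate,
        "stage": rec.stage,
    }, indent=2) + "\n")
    return [path, sidecar]


def read_recording(path: str | Path) -> Recording:
    """Read a recording from TSV + JSON sidecar, or from EDF (needs mne)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return Recording(labels=tuple(meta["labels"]),
                     sampling_rate=float(meta["sampling_rate_hz"]),
                     data=data, stage=meta.get("stage"))


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(labels=tuple(raw.ch_names),
                     sampling_rate=float(raw.info["sfreq"]),
                     data=raw.get_data())


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> list[Path]:
    """Write a connectivity matrix as labeled TSV + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(m.values, index=list(m.labels), columns=list(m.labels))
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "stage": m.stage,
        "band": m.band,
        "normalized": m.normalized,
        "mi_units": m.mi_units,
    }, indent=2) + "\n")
    return [path, sidecar]


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ConnectivityMatrix(
        labels=tuple(str(c) for c in df.columns),
        values=df.to_numpy(dtype=float),
        band=meta.get("band"), stage=meta.get("stage"),
        normalized=bool(meta.get("normalized", False)),
        mi_units=meta.get("mi_units", "nats"))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a subjects x conditions measurement table as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
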