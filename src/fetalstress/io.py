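"""CSV interchange for ECG, RR, FSI and event tables.

The canonical dialect is plain CSV with a header row, UTF-8, '.' decimal
separator.  Columns:

* ECG:    time_s, voltage
* RR:     beat_time_s, rr_ms, flag
* events: subject_id, time_s, ph, po2, pco2, lactate, base_deficit, hr, map
* FSI:    time_s, fsi_inst, auc_min, valid  /  time_s, fsi_averaged
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg_rr import ECGRecord, RRSeries
from .fsi_core import FSIConfig, FSISeries
from .synth import SampleEvent

__all__ = [
    "read_ecg_csv",
    "read_rr_csv",
    "write_rr_csv",
    "read_events_csv",
    "write_events_csv",
    "write_fsi_csv",
    "read_config",
    "write_config",
    "write_manifest",
    "file_sha256",
]


def read_ecg_csv(path: str | Path) -> ECGRecord:
    """Read a 2-column (time_s, voltage) CSV; sampling rate from the grid."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_s, voltage")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: too few samples")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValueError(f"{path}: time column must be increasing")
    return ECGRecord(sample_rate=1.0 / dt, samples=v, start_time=float(t[0]))


def read_rr_csv(path: str | Path) -> RRSeries:
    return RRSeries.from_frame(pd.read_csv(path))


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    rr.to_frame().to_csv(path, index=False)


_EVENT_COLS = [
    "subject_id", "time_s", "ph", "po2", "pco2", "lactate",
    "base_deficit", "hr", "map",
]


def read_events_csv(path: str | Path) -> list[SampleEvent]:
    df = pd.read_csv(path)
    missing = set(_EVENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SampleEvent(
            subject_id=str(r.subject_id),
            time=float(r.time_s),
            ph=float(r.ph),
            po2=float(r.po2),
            pco2=float(r.pco2),
            lactate=float(r.lactate),
            base_deficit=float(r.base_deficit),
            hr=float(r.hr),
            map=float(r.map),
        )
        for r in df.itertuples()
    ]


def write_events_csv(events: list[SampleEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in events],
            "time_s": [e.time for e in events],
            "ph": [e.ph for e in events],
            "po2": [e.po2 for e in events],
            "pco2": [e.pco2 for e in events],
            "lactate": [e.lactate for e in events],
            "base_deficit": [e.base_deficit for e in events],
            "hr": [e.hr for e in events],
            "map": [e.map for e in events],
        }
    ).to_csv(path, index=False)


def write_fsi_csv(series: FSISeries, out_dir: str | Path) -> tuple[Path, Path]:
    """Write fsi_inst.csv and fsi_averaged.csv; returns the two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inst = out / "fsi_inst.csv"
    pd.DataFrame(
        {
            "time_s": series.times,
            "fsi_inst": series.fsi_inst,
            "auc_min": series.auc_min,
            "valid": series.valid.astype(int),
        }
    ).to_csv(inst, index=False)
    avg = out / "fsi_averaged.csv"
    pd.DataFrame(
        {"time_s": series.avg_times, "fsi_averaged": series.avg_values}
    ).to_csv(avg, index=False)
    return inst, avg


def write_config(cfg: FSIConfig, path: str | Path) -> None:
    """Flat key=value file mirroring FSIConfig fields."""
    lines = []
    for name in cfg.__dataclass_fields__:
        val = getattr(cfg, name)
        if isinstance(val, tuple):
            val = ",".join(str(v) for v in val)
        lines.append(f"{name} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> FSIConfig:
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, raw = line.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key not in FSIConfig.__dataclass_fields__:
            raise ValueError(f"{path}: unknown config key {key!r}")
        if key == "clamp":
            kwargs[key] = tuple(float(v) for v in raw.split(","))
        elif key == "wavelet":
            kwargs[key] = raw
        elif key == "n_subareas":
            kwargs[key] = int(raw)
        else:
            kwargs[key] = float(raw)
    return FSIConfig(**kwargs)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (config, seeds, input hashes, versions)."""
    import fetalstress

    payload = {"fetalstress_version": fetalstress.__version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
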