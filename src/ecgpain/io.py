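"""Plain-text serialization: recordings as CSV, annotations as JSON.

Recording CSV layout::

    # fs=1000.0
    # participant=P01
    # session=1
    time_s,amplitude_mV
    0.000,0.01234
    ...

Triggers and fiducials share one JSON schema so externally produced
fiducials can be scored against the generator's ground truth::

    {"epochs": [{"label": "baseline", "start_sample": 0, "end_sample": 300000}],
     "fiducials": {"R_peak": [...], ...}}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ecgpain.delineate import FiducialSet
from ecgpain.features import FEATURE_COLUMNS, META_COLUMNS
from ecgpain.preprocess import FilterSpec
from ecgpain.recording import EcgRecording
from ecgpain.synth import GroundTruth


def write_recording_csv(rec: EcgRecording, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        fh.write(f"# participant={rec.participant}\n")
        fh.write(f"# session={rec.session}\n")
        fh.write("time_s,amplitude_mV\n")
        np.savetxt(fh, np.column_stack([t, rec.signal]), fmt="%.3f,%.5f")


def read_recording_csv(path: str | Path,
                       triggers: dict[str, tuple[int, int]] | None = None
                       ) -> EcgRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            skip += 1
    data = pd.read_csv(path, skiprows=skip)
    return EcgRecording(
        signal=data["amplitude_mV"].to_numpy(),
        fs=float(meta.get("fs", 1000.0)),
        participant=meta.get("participant", "P00"),
        session=int(meta.get("session", 1)),
        triggers=triggers or {},
    )


def _annotations_dict(epochs: dict[str, tuple[int, int]],
                      fiducials: dict[str, np.ndarray] | None) -> dict:
    out = {
        "epochs": [
            {"label": lab, "start_sample": int(s), "end_sample": int(e)}
            for lab, (s, e) in epochs.items()
        ]
    }
    if fiducials is not None:
        out["fiducials"] = {k: [int(v) for v in arr] for k, arr in fiducials.items()}
    return out


def write_triggers_json(epochs: dict[str, tuple[int, int]],
                        path: str | Path) -> None:
    Path(path).write_text(json.dumps(_annotations_dict(epochs, None), indent=1))


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_annotations_dict(truth.epochs, truth.fiducials), indent=1)
    )


def write_fiducials_json(fids: FiducialSet, path: str | Path,
                         epochs: dict[str, tuple[int, int]] | None = None) -> None:
    payload = _annotations_dict(epochs or {}, fids.fiducials)
    payload["n_dropped"] = fids.n_dropped
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations_json(path: str | Path
                          ) -> tuple[dict[str, tuple[int, int]],
                                     dict[str, np.ndarray] | None]:
    """Read the shared triggers/fiducials schema."""
    payload = json.loads(Path(path).read_text())
    epochs = {
        item["label"]: (int(item["start_sample"]), int(item["end_sample"]))
        for item in payload.get("epochs", [])
    }
    fids = payload.get("fiducials")
    if fids is not None:
        fids = {k: np.asarray(v, dtype=np.int64) for k, v in fids.items()}
    return epochs, fids


def write_filter_json(spec: FilterSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=1))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in list(META_COLUMNS) + FEATURE_COLUMNS + ["label"]
            if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "label" in table.columns:
        table["label"] = table["label"].astype("Int64")
    return table
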