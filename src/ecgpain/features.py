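"""Windowed morphological ECG features with baseline normalization.

Each protocol epoch is sliced into 20 s windows with 75 % overlap (5 s step)
and 21 features are computed per window from the delineated fiducials:

* ``{P,R,S,T}_peaks``     — number of peaks of that wave in the window;
* ``{P,R,S,T}_amplitude`` — mean signal value at those peaks (mV);
* ``{P,R,S,T}_distance``  — mean distance in samples between consecutive
  same-type peaks (both members in-window);
* ``{P,R,T}_onsetamp`` / ``{P,R,T}_offsetamp`` — mean signal value at wave
  onsets / offsets (mV);
* ``{P,R,T}_onoffdist``   — mean onset-to-offset distance in samples per
  wave instance (the wave's width; see the package notes for the reading of
  this definition).

Every feature is then divided by its mean over the baseline-epoch windows of
the same participant-session.  Rows with any undefined feature are dropped,
never imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ecgpain.delineate import FiducialSet
from ecgpain.synth import GroundTruth

WAVES_FULL = ("P", "R", "S", "T")
WAVES_EDGED = ("P", "R", "T")

#: The 21 feature columns, in canonical order.
FEATURE_COLUMNS = (
    [f"{w}_peaks" for w in WAVES_FULL]
    + [f"{w}_amplitude" for w in WAVES_FULL]
    + [f"{w}_distance" for w in WAVES_FULL]
    + [f"{w}_onsetamp" for w in WAVES_EDGED]
    + [f"{w}_offsetamp" for w in WAVES_EDGED]
    + [f"{w}_onoffdist" for w in WAVES_EDGED]
)

META_COLUMNS = ("participant", "session", "epoch", "window_start")

#: Class labels: baseline is the negative class, CPT the positive one.
LABELS = {"baseline": 0, "cpt": 1}


class NormalizationError(ValueError):
    """A baseline reference is zero or missing."""


class DatasetError(ValueError):
    """The assembled dataset lacks one of the two classes."""


def make_windows(epoch_start: int, epoch_end: int, fs: float,
                 window_s: float = 20.0, overlap: float = 0.75
                 ) -> list[tuple[int, int]]:
    """Half-open sample intervals of sliding windows fully inside the epoch.

    Step = ``window_s * (1 - overlap)``; a trailing partial window is
    dropped, so an epoch of length L yields ``floor((L - W)/step) + 1``
    windows.  Returns an empty list (with a warning) for epochs shorter than
    one window.
    """
    if window_s <= 0:
        raise ValueError("window length must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    win = int(round(window_s * fs))
    step = int(round(window_s * (1.0 - overlap) * fs))
    length = epoch_end - epoch_start
    if length < win:
        warnings.warn(
            f"epoch of {length} samples shorter than one {win}-sample window",
            stacklevel=2,
        )
        return []
    starts = range(epoch_start, epoch_end - win + 1, step)
    return [(s, s + win) for s in starts]


def extract_features(fiducials: FiducialSet | GroundTruth,
                     window: tuple[int, int],
                     signal: np.ndarray) -> dict[str, float]:
    """Compute the 21 features for one window.

    Features requiring at least two events (distances) with fewer than two
    events in-window come back as NaN; such rows are flagged incomplete and
    dropped downstream.
    """
    start, end = window
    fids = fiducials.fiducials
    row: dict[str, float] = {}

    def in_window(arr: np.ndarray) -> np.ndarray:
        return arr[(arr >= start) & (arr < end)]

    for w in WAVES_FULL:
        peaks = in_window(fids[f"{w}_peak"])
        row[f"{w}_peaks"] = float(peaks.size)
        row[f"{w}_amplitude"] = float(signal[peaks].mean()) if peaks.size else np.nan
        row[f"{w}_distance"] = (
            float(np.diff(peaks).mean()) if peaks.size >= 2 else np.nan
        )

    for w in WAVES_EDGED:
        onsets_all = fids[f"{w}_onset"]
        offsets_all = fids[f"{w}_offset"]
        onsets = in_window(onsets_all)
        offsets = in_window(offsets_all)
        row[f"{w}_onsetamp"] = float(signal[onsets].mean()) if onsets.size else np.nan
        row[f"{w}_offsetamp"] = float(signal[offsets].mean()) if offsets.size else np.nan
        # onset-to-offset duration per wave instance, both edges in-window
        mask = (onsets_all >= start) & (onsets_all < end) \
            & (offsets_all >= start) & (offsets_all < end)
        widths = offsets_all[mask] - onsets_all[mask]
        row[f"{w}_onoffdist"] = float(widths.mean()) if widths.size else np.nan

    return row


def build_feature_table(fiducials: FiducialSet | GroundTruth,
                        signal: np.ndarray,
                        epochs: dict[str, tuple[int, int]],
                        participant: str, session: int,
                        fs: float,
                        window_s: float = 20.0,
                        overlap: float = 0.75) -> pd.DataFrame:
    """One row per window across all epochs of one recording."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, (estart, eend) in epochs.items():
            for win in make_windows(estart, eend, fs, window_s, overlap):
                row = extract_features(fiducials, win, signal)
                row.update(participant=participant, session=session,
                           epoch=label, window_start=win[0])
                rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=list(META_COLUMNS) + FEATURE_COLUMNS)
    return table[list(META_COLUMNS) + FEATURE_COLUMNS]


def normalize_by_baseline(table: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide every feature by its baseline-epoch mean per participant-session.

    Returns the normalized table and the reference table (one row per
    participant-session with the 21 baseline means).  Raises
    :class:`NormalizationError` when a participant-session has no baseline
    windows or a zero baseline mean.
    """
    feats = list(FEATURE_COLUMNS)
    refs = []
    out_parts = []
    for (participant, session), group in table.groupby(["participant", "session"]):
        base = group[group["epoch"] == "baseline"]
        if base.empty:
            raise NormalizationError(
                f"no baseline windows for participant {participant} session {session}"
            )
        means = base[feats].mean()
        zero = means[means == 0]
        if not zero.empty:
            raise NormalizationError(
                f"zero baseline mean for feature(s) {list(zero.index)} "
                f"(participant {participant}, session {session})"
            )
        normalized = group.copy()
        normalized[feats] = group[feats] / means
        out_parts.append(normalized)
        ref = means.to_dict()
        ref.update(participant=participant, session=session)
        refs.append(ref)
    normalized_table = pd.concat(out_parts).sort_index()
    reference = pd.DataFrame(refs)[["participant", "session"] + feats]
    return normalized_table, reference


def assemble_dataset(normalized: pd.DataFrame,
                     epochs: tuple[str, ...] = ("baseline", "cpt")
                     ) -> pd.DataFrame:
    """Restrict to the labeled epochs, attach the class label, drop NaN rows.

    Baseline rows get label 0, CPT rows label 1; rows from other requested
    epochs keep a missing label.  The number of dropped incomplete rows is
    recorded in ``DataFrame.attrs['n_dropped']``.
    """
    sub = normalized[normalized["epoch"].isin(epochs)].copy()
    n_before = len(sub)
    sub = sub.dropna(subset=list(FEATURE_COLUMNS))
    n_dropped = n_before - len(sub)
    sub["label"] = sub["epoch"].map(LABELS).astype("Int64")
    labeled = sub[sub["label"].notna()]
    if set(epochs) >= {"baseline", "cpt"}:
        present = set(labeled["label"].unique())
        if present != {0, 1}:
            raise DatasetError(
                f"need both classes in the dataset, found labels {sorted(present)}"
            )
    sub.attrs["n_dropped"] = n_dropped
    return sub
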