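"""R-peak detection and P/QRS/T delineation.

R detection is a Pan-Tompkins-style chain (derivative, squaring, moving
window integration, adaptive two-level threshold with a 200 ms refractory
period) followed by refinement to the local maximum of the band-passed
signal.  Delineation then searches bounded physiological windows around each
R peak for the P maximum, S trough and T maximum, and places onsets/offsets
where the signal crosses a configurable fraction of the local wave
prominence.  Beats whose full fiducial set cannot be located are dropped and
counted, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ecgpain.synth import FIDUCIAL_KEYS


class DelineationError(ValueError):
    """Delineation cannot proceed on this input."""


class InputError(ValueError):
    """Invalid signal input."""


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Detect one index per heartbeat at the local maximum of the QRS.

    A refractory period of 200 ms is enforced.  Returns an empty array (with
    a warning) when no QRS-like activity is present.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise InputError("sampling rate must be positive")
    if signal.size < 2 * fs:
        raise InputError("signal shorter than 2 s")
    if not np.any(signal):
        warnings.warn("all-zero signal: no R peaks detected", stacklevel=2)
        return np.array([], dtype=np.int64)

    refractory = int(round(0.2 * fs))

    # Derivative -> squaring -> moving-window integration (150 ms, centered
    # so integrated peaks stay aligned with the QRS).
    deriv = np.gradient(signal)
    squared = deriv * deriv
    win = max(1, int(round(0.15 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    # Candidate peaks of the integrated energy, at least a refractory apart.
    from scipy.signal import find_peaks

    candidates, _ = find_peaks(mwi, distance=refractory)
    if candidates.size == 0:
        warnings.warn("no QRS candidates found", stacklevel=2)
        return np.array([], dtype=np.int64)

    # Adaptive two-level threshold (signal level / noise level estimates).
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    accepted: list[int] = []
    for cand in candidates:
        level = mwi[cand]
        thr = npki + 0.25 * (spki - npki)
        if level > thr:
            accepted.append(int(cand))
            spki = 0.125 * level + 0.875 * spki
        else:
            npki = 0.125 * level + 0.875 * npki
    if not accepted:
        warnings.warn("no QRS passed the adaptive threshold", stacklevel=2)
        return np.array([], dtype=np.int64)

    # Polarity: refine against the dominant QRS deflection direction.
    probe = signal[np.asarray(accepted)]
    flip = np.median(probe) < 0 and np.median(np.abs(signal[np.asarray(accepted)])) > 0
    x = -signal if flip else signal

    # Refine each candidate to the local signal maximum.
    half = int(round(0.075 * fs))
    refined: list[int] = []
    for cand in accepted:
        lo = max(0, cand - half)
        hi = min(signal.size, cand + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))

    # Deduplicate within the refractory period, keeping the taller peak.
    refined.sort()
    peaks: list[int] = []
    for idx in refined:
        if peaks and idx - peaks[-1] < refractory:
            if x[idx] > x[peaks[-1]]:
                peaks[-1] = idx
        else:
            peaks.append(idx)
    return np.asarray(peaks, dtype=np.int64)


@dataclass(frozen=True)
class DelineationConfig:
    """Search windows (seconds, relative to R) and the edge threshold."""

    p_window: tuple[float, float] = (-0.25, -0.06)
    q_window: tuple[float, float] = (-0.08, -0.005)
    s_window: tuple[float, float] = (0.0, 0.12)
    t_window: tuple[float, float] = (0.12, 0.45)
    edge_fraction: float = 0.1      # fraction of wave prominence for onsets/offsets
    edge_reach_s: float = 0.25      # how far beyond a peak an edge may be searched


@dataclass
class FiducialSet:
    """Arrays of fiducial sample indices per type, all beats complete.

    Within any beat the ordering
    P_onset < P_peak < P_offset <= R_onset < R_peak < S_peak <= R_offset
    <= T_onset < T_peak < T_offset holds; each array is strictly increasing.
    """

    fiducials: dict[str, np.ndarray]
    fs: float
    n_dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return len(self.fiducials["R_peak"])

    def __getitem__(self, key: str) -> np.ndarray:
        return self.fiducials[key]

    def check_ordering(self) -> bool:
        """Verify the within-beat ordering and per-type strict monotonicity."""
        f = self.fiducials
        for i in range(self.n_beats):
            ok = (f["P_onset"][i] < f["P_peak"][i] < f["P_offset"][i]
                  <= f["R_onset"][i] < f["R_peak"][i] < f["S_peak"][i]
                  <= f["R_offset"][i] <= f["T_onset"][i] < f["T_peak"][i]
                  < f["T_offset"][i])
            if not ok:
                return False
        return all(
            arr.size < 2 or bool(np.all(np.diff(arr) > 0))
            for arr in f.values()
        )


def _edge_search(x: np.ndarray, base: float, peak_idx: int, thr: float,
                 bound: int, direction: int, sign: float) -> int | None:
    """Nearest sample from ``peak_idx`` toward ``bound`` where the signed
    deflection ``sign * (x - base)`` has decayed to <= ``thr``.

    One-sided so that a small bias in the baseline estimate cannot prevent
    the crossing from being found.
    """
    if direction < 0:
        seg = sign * (x[bound:peak_idx] - base) <= thr
        hits = np.nonzero(seg)[0]
        return bound + int(hits[-1]) if hits.size else None
    seg = sign * (x[peak_idx + 1:bound] - base) <= thr
    hits = np.nonzero(seg)[0]
    return peak_idx + 1 + int(hits[0]) if hits.size else None


def delineate_waves(signal: np.ndarray, r_peaks: np.ndarray, fs: float,
                    config: DelineationConfig | None = None) -> FiducialSet:
    """Locate the 10 fiducials for every beat anchored at a detected R peak.

    Incomplete beats (a missing extremum, an edge that never crosses the
    threshold, or an ordering violation) are dropped and tallied in
    ``drop_reasons``.
    """
    signal = np.asarray(signal, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if r_peaks.size < 2:
        raise DelineationError("need at least 2 R peaks to delineate")
    config = config or DelineationConfig()

    if np.median(signal[r_peaks]) < 0:
        raise DelineationError(
            "detected R peaks have negative polarity; invert the signal first"
        )

    n = signal.size
    s = lambda sec: int(round(sec * fs))  # noqa: E731
    reach = s(config.edge_reach_s)
    frac = config.edge_fraction

    fid_lists: dict[str, list[int]] = {key: [] for key in FIDUCIAL_KEYS}
    dropped = 0
    reasons: dict[str, int] = {}

    def drop(reason: str) -> None:
        nonlocal dropped
        dropped += 1
        reasons[reason] = reasons.get(reason, 0) + 1

    chunk = max(2, s(0.03))
    stride = max(1, s(0.01))
    # Smoothed copy for baseline estimation only: a 10 ms boxcar suppresses
    # broadband noise so the flattest chunk is a true isoelectric segment
    # rather than the (noise-masked) top of the P wave.
    smooth_win = max(1, s(0.01))
    smoothed = np.convolve(signal, np.ones(smooth_win) / smooth_win, mode="same")

    def isoelectric_level(r: int) -> float:
        """Mean of the flattest 30 ms chunk in the pre-QRS context."""
        lo_ctx = max(0, r - s(0.35))
        hi_ctx = max(lo_ctx + chunk, r - s(0.04))
        seg = smoothed[lo_ctx:min(hi_ctx, n)]
        if seg.size < chunk:
            return float(np.median(seg)) if seg.size else 0.0
        starts = np.arange(0, seg.size - chunk + 1, stride)
        windows = np.lib.stride_tricks.sliding_window_view(seg, chunk)[starts]
        flattest = windows[int(np.argmin(windows.var(axis=1)))]
        return float(flattest.mean())

    for bi, r in enumerate(r_peaks):
        base = isoelectric_level(int(r))

        def extremum(window: tuple[float, float], mode: str) -> int | None:
            lo = max(0, r + s(window[0]))
            hi = min(n, r + s(window[1]) + 1)
            if hi - lo < 2:
                return None
            seg = signal[lo:hi]
            return lo + int(np.argmax(seg) if mode == "max" else np.argmin(seg))

        p_peak = extremum(config.p_window, "max")
        q_trough = extremum(config.q_window, "min")
        s_peak = extremum(config.s_window, "min")
        t_peak = extremum(config.t_window, "max")
        if None in (p_peak, q_trough, s_peak, t_peak):
            drop("window_out_of_bounds")
            continue

        def edges(peak: int, left_bound: int, right_bound: int
                  ) -> tuple[int | None, int | None]:
            deflection = signal[peak] - base
            sign = 1.0 if deflection >= 0 else -1.0
            thr = frac * abs(deflection)
            onset = _edge_search(signal, base, peak, thr,
                                 max(0, left_bound), -1, sign)
            offset = _edge_search(signal, base, peak, thr,
                                  min(n, right_bound), +1, sign)
            return onset, offset

        p_on, p_off = edges(p_peak, p_peak - reach, min(q_trough, p_peak + reach))
        r_on, _ = edges(q_trough, q_trough - s(0.08), q_trough + 1)
        _, r_off = edges(s_peak, s_peak, s_peak + s(0.10))
        next_r = r_peaks[bi + 1] if bi + 1 < r_peaks.size else n
        t_on, t_off = edges(t_peak, max(s_peak, t_peak - reach),
                            min(int(next_r) - s(0.10), t_peak + reach))

        fids = {
            "P_peak": p_peak, "R_peak": int(r), "S_peak": s_peak, "T_peak": t_peak,
            "P_onset": p_on, "P_offset": p_off,
            "R_onset": r_on, "R_offset": r_off,
            "T_onset": t_on, "T_offset": t_off,
        }
        missing = [k for k, v in fids.items() if v is None]
        if missing:
            drop("edge_not_found:" + ",".join(missing))
            continue
        ordered = (fids["P_onset"] < fids["P_peak"] < fids["P_offset"]
                   <= fids["R_onset"] < fids["R_peak"] < fids["S_peak"]
                   <= fids["R_offset"] <= fids["T_onset"] < fids["T_peak"]
                   < fids["T_offset"])
        if not ordered:
            drop("ordering_violation")
            continue
        if fid_lists["R_peak"] and any(
            fids[k] <= fid_lists[k][-1] for k in FIDUCIAL_KEYS
        ):
            drop("non_monotone")
            continue
        for key, val in fids.items():
            fid_lists[key].append(int(val))

    fiducials = {key: np.asarray(v, dtype=np.int64) for key, v in fid_lists.items()}
    return FiducialSet(fiducials=fiducials, fs=fs, n_dropped=dropped,
                       drop_reasons=reasons)
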