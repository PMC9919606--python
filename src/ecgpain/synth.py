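"""Synthetic protocol-structured ECG cohorts with ground-truth fiducials.

Each heartbeat is a sum of five Gaussian wave components (P, Q, R, S, T)
placed around the R peak, in the style of the classic sum-of-kernels ECG
simulators.  Because the waveform is analytic, every fiducial (peak and the
point where a wave component falls to a documented fraction of its height)
is known exactly and can be used to score a delineator.

A controllable "cold pressor" effect modulates heart rate, S/T/R amplitudes
and the signal level at the T offset during the ``cpt`` epoch only.  The
effect sizes are invented (the modelled study population is not available)
and are chosen so that those five quantities become informative downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ecgpain.recording import EPOCH_LABELS, EcgRecording

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: Fiducial types carried by the ground truth (and by the delineator).
FIDUCIAL_KEYS = (
    "P_peak", "R_peak", "S_peak", "T_peak",
    "P_onset", "P_offset", "R_onset", "R_offset", "T_onset", "T_offset",
)

#: Fraction of a wave component's peak height at which onset/offset
#: ground truth is defined (configurable via ``BeatModel.edge_fraction``).
DEFAULT_EDGE_FRACTION = 0.05


class ParameterError(ValueError):
    """Invalid generator parameter."""


@dataclass(frozen=True)
class Wave:
    """One Gaussian wave component: ``amp * exp(-((t - center)/sigma)^2 / 2)``."""

    amp: float      # mV, sign carries polarity
    sigma: float    # s
    center: float   # s, offset relative to the R peak


@dataclass
class BeatModel:
    """Per-beat morphology plus rhythm parameters.

    Invariants: all widths positive, heart rate in [30, 200] bpm, R amplitude
    positive, wave centers strictly ordered P < Q < R < S < T.
    """

    waves: dict[str, Wave] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    heart_rate: float = 60.0        # bpm
    rr_jitter: float = 0.03         # sd of multiplicative log-normal RR noise
    edge_fraction: float = DEFAULT_EDGE_FRACTION

    def __post_init__(self) -> None:
        missing = [w for w in WAVE_NAMES if w not in self.waves]
        if missing:
            raise ParameterError(f"missing wave components: {missing}")
        for name, wave in self.waves.items():
            if wave.sigma <= 0:
                raise ParameterError(f"{name}-wave width must be positive")
        if not 30.0 <= self.heart_rate <= 200.0:
            raise ParameterError(
                f"heart rate {self.heart_rate} bpm outside [30, 200]"
            )
        if self.waves["R"].amp <= 0:
            raise ParameterError("R amplitude must be positive")
        centers = [self.waves[w].center for w in WAVE_NAMES]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ParameterError("wave centers must be strictly ordered P < Q < R < S < T")
        if self.rr_jitter < 0:
            raise ParameterError("rr_jitter must be non-negative")
        if not 0 < self.edge_fraction < 1:
            raise ParameterError("edge_fraction must lie in (0, 1)")

    @property
    def edge_halfwidth_factor(self) -> float:
        """Multiples of sigma at which a Gaussian falls to ``edge_fraction``."""
        return math.sqrt(-2.0 * math.log(self.edge_fraction))


#: Default morphology, loosely a lead-II adult beat (amplitudes in mV, times in s).
DEFAULT_WAVES: dict[str, Wave] = {
    "P": Wave(amp=0.15, sigma=0.025, center=-0.20),
    "Q": Wave(amp=-0.10, sigma=0.010, center=-0.04),
    "R": Wave(amp=1.00, sigma=0.012, center=0.00),
    "S": Wave(amp=-0.25, sigma=0.012, center=0.04),
    "T": Wave(amp=0.30, sigma=0.060, center=0.30),
}


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative CPT-epoch modulation. Identity = all factors 1, shift 0.

    Defaults are synthetic (no quantitative effect sizes exist for the
    modelled protocol): heart rate x1.25, S amplitude x0.7, T amplitude x0.8,
    R amplitude x0.9 and a -0.05 mV level shift at the T offset.
    """

    hr_factor: float = 1.25
    s_amp_factor: float = 0.7
    t_amp_factor: float = 0.8
    r_amp_factor: float = 0.9
    t_offset_shift: float = -0.05   # mV

    def __post_init__(self) -> None:
        for name in ("hr_factor", "s_amp_factor", "t_amp_factor", "r_amp_factor"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @classmethod
    def identity(cls) -> "EffectSpec":
        return cls(hr_factor=1.0, s_amp_factor=1.0, t_amp_factor=1.0,
                   r_amp_factor=1.0, t_offset_shift=0.0)

    @property
    def is_identity(self) -> bool:
        return (self.hr_factor == self.s_amp_factor == self.t_amp_factor
                == self.r_amp_factor == 1.0) and self.t_offset_shift == 0.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: baseline wander + powerline + broadband white noise."""

    wander_amp: float = 0.3         # mV
    wander_freq: float = 0.15       # Hz, must stay below the analysis high-pass
    powerline_amp: float = 0.05     # mV
    powerline_freq: float = 50.0    # Hz
    broadband_sd: float = 0.02      # mV

    def __post_init__(self) -> None:
        if min(self.wander_amp, self.powerline_amp, self.broadband_sd) < 0:
            raise ParameterError("noise amplitudes must be non-negative")
        if not 0 < self.wander_freq < 0.5:
            raise ParameterError("wander frequency must lie in (0, 0.5) Hz")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(wander_amp=0.0, powerline_amp=0.0, broadband_sd=0.0)


@dataclass(frozen=True)
class ProtocolLayout:
    """Ordered epoch labels and durations in seconds, plus the sampling rate.

    Defaults follow the cold-pressor protocol: baseline 300 s, warm1 120 s,
    cpt up to 120 s, warm2 120 s, rest 300 s at 1000 Hz.
    """

    epochs: tuple[tuple[str, float], ...] = (
        ("baseline", 300.0), ("warm1", 120.0), ("cpt", 120.0),
        ("warm2", 120.0), ("rest", 300.0),
    )
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        for label, dur in self.epochs:
            if dur <= 0:
                raise ParameterError(f"epoch {label!r} must have positive duration")
            if label == "cpt" and dur > 120.0:
                raise ParameterError("cpt duration cannot exceed 120 s")

    @property
    def total_duration_s(self) -> float:
        return sum(dur for _, dur in self.epochs)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.fs))

    def intervals(self) -> dict[str, tuple[int, int]]:
        """Half-open sample intervals per epoch, contiguous from sample 0."""
        out: dict[str, tuple[int, int]] = {}
        t = 0.0
        for label, dur in self.epochs:
            start = int(round(t * self.fs))
            end = int(round((t + dur) * self.fs))
            out[label] = (start, end)
            t += dur
        return out

    def with_cpt_duration(self, seconds: float) -> "ProtocolLayout":
        epochs = tuple(
            (lab, seconds if lab == "cpt" else dur) for lab, dur in self.epochs
        )
        return replace(self, epochs=epochs)


@dataclass
class GroundTruth:
    """True sample indices of the 10 fiducials per beat, plus the epoch map.

    Every beat is complete: all fiducial arrays have equal length and are
    strictly increasing.
    """

    fiducials: dict[str, np.ndarray]
    epochs: dict[str, tuple[int, int]]
    fs: float

    @property
    def n_beats(self) -> int:
        return len(self.fiducials["R_peak"])

    def beats_in(self, label: str) -> np.ndarray:
        """Boolean mask of beats whose R peak lies inside the given epoch."""
        start, end = self.epochs[label]
        r = self.fiducials["R_peak"]
        return (r >= start) & (r < end)


def _beat_time_scale(rr_s: float) -> float:
    """Rate-dependent beat compression (square-root law, capped at 1).

    Keeps the T wave clear of the next beat's P wave at fast rates, mirroring
    physiological QT shortening, while a 60 bpm beat is left untouched.
    """
    return min(1.0, math.sqrt(rr_s))


def _beat_fiducial_offsets(model: BeatModel, scale: float) -> dict[str, float]:
    """Fiducial time offsets (s, relative to R peak) for one beat."""
    k = model.edge_halfwidth_factor
    w = {name: replace(wv, center=wv.center * scale, sigma=wv.sigma * scale)
         for name, wv in model.waves.items()}
    return {
        "P_peak": w["P"].center,
        "R_peak": w["R"].center,
        "S_peak": w["S"].center,
        "T_peak": w["T"].center,
        "P_onset": w["P"].center - k * w["P"].sigma,
        "P_offset": w["P"].center + k * w["P"].sigma,
        # QRS onset/offset: outer edge of the Q trough and of the S trough
        "R_onset": w["Q"].center - k * w["Q"].sigma,
        "R_offset": w["S"].center + k * w["S"].sigma,
        "T_onset": w["T"].center - k * w["T"].sigma,
        "T_offset": w["T"].center + k * w["T"].sigma,
    }


def _beat_waves(model: BeatModel, scale: float, effect_on: bool,
                effect: EffectSpec) -> list[Wave]:
    """Wave components of one beat with the CPT effect applied if active."""
    w = {name: replace(wv, center=wv.center * scale, sigma=wv.sigma * scale)
         for name, wv in model.waves.items()}
    waves = [w["P"], w["Q"]]
    if effect_on:
        waves.append(replace(w["R"], amp=w["R"].amp * effect.r_amp_factor))
        waves.append(replace(w["S"], amp=w["S"].amp * effect.s_amp_factor))
        waves.append(replace(w["T"], amp=w["T"].amp * effect.t_amp_factor))
        if effect.t_offset_shift != 0.0:
            # Narrow repolarization-tail bump that moves the signal level at
            # the T offset without displacing the analytic T fiducials much.
            k = model.edge_halfwidth_factor
            waves.append(Wave(amp=effect.t_offset_shift, sigma=w["T"].sigma / 2.0,
                              center=w["T"].center + k * w["T"].sigma))
    else:
        waves.extend([w["R"], w["S"], w["T"]])
    return waves


def synth_beat_train(
    beat: BeatModel,
    layout: ProtocolLayout,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a clean beat train over the protocol layout.

    R peaks are laid out sequentially with RR = 60 / HR x exp(N(0, jitter));
    the effect's heart-rate factor shortens RR inside the ``cpt`` epoch and
    its amplitude factors rescale the S, T and R components of beats whose R
    peak falls inside that epoch.  Returns the clean signal and the analytic
    ground truth for every beat whose 10 fiducials all fit in the signal.
    """
    effect = effect if effect is not None else EffectSpec.identity()
    rng = np.random.default_rng(seed)
    fs = layout.fs
    n = layout.n_samples
    epochs = layout.intervals()
    cpt = epochs.get("cpt")

    def in_cpt(sample: float) -> bool:
        return cpt is not None and cpt[0] <= sample < cpt[1]

    base_rr = 60.0 / beat.heart_rate

    # Sequential R-peak placement; the RR step out of a beat uses that beat's
    # epoch so rate changes take hold at the CPT boundary.
    r_times: list[float] = []
    t = 0.5 * base_rr
    total_s = layout.total_duration_s
    while t < total_s:
        r_times.append(t)
        rr = base_rr
        if in_cpt(t * fs):
            rr /= effect.hr_factor
        if beat.rr_jitter > 0:
            rr *= math.exp(rng.normal(0.0, beat.rr_jitter))
        t += rr

    signal = np.zeros(n)
    fid_lists: dict[str, list[int]] = {key: [] for key in FIDUCIAL_KEYS}

    for rt in r_times:
        r_sample = rt * fs
        effect_on = in_cpt(r_sample)
        rr_eff = base_rr / effect.hr_factor if effect_on else base_rr
        scale = _beat_time_scale(rr_eff)
        offsets = _beat_fiducial_offsets(beat, scale)
        fid_samples = {key: int(round((rt + off) * fs)) for key, off in offsets.items()}
        complete = all(0 <= s < n for s in fid_samples.values())

        for wave in _beat_waves(beat, scale, effect_on, effect):
            center = rt + wave.center
            lo = max(0, int(math.floor((center - 5 * wave.sigma) * fs)))
            hi = min(n, int(math.ceil((center + 5 * wave.sigma) * fs)) + 1)
            if lo >= hi:
                continue
            tt = np.arange(lo, hi) / fs
            signal[lo:hi] += wave.amp * np.exp(-0.5 * ((tt - center) / wave.sigma) ** 2)

        if complete:
            for key, s in fid_samples.items():
                fid_lists[key].append(s)

    fiducials = {key: np.asarray(v, dtype=np.int64) for key, v in fid_lists.items()}
    return signal, GroundTruth(fiducials=fiducials, epochs=epochs, fs=fs)


def add_noise(signal: np.ndarray, noise: NoiseSpec, seed: int = 0,
              fs: float = 1000.0) -> np.ndarray:
    """Add baseline wander, powerline interference and white noise."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ParameterError("signal must be non-empty")
    rng = np.random.default_rng(seed)
    t = np.arange(signal.size)
    out = signal.copy()
    # Phases are seeded so realizations are reproducible.
    if noise.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.wander_amp * np.sin(2 * np.pi * noise.wander_freq * t / fs + phase)
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t / fs + phase
        )
    if noise.broadband_sd > 0:
        out += rng.normal(0.0, noise.broadband_sd, size=signal.size)
    return out


def _draw_beat_model(rng: np.random.Generator, template: BeatModel) -> BeatModel:
    """Participant-level morphology: perturb amplitudes/widths, draw a resting HR."""
    waves: dict[str, Wave] = {}
    for name, wave in template.waves.items():
        amp = wave.amp * float(np.exp(rng.normal(0.0, 0.15)))
        sigma = wave.sigma * float(np.exp(rng.normal(0.0, 0.08)))
        waves[name] = Wave(amp=amp, sigma=sigma, center=wave.center)
    hr = float(rng.uniform(55.0, 80.0))
    return BeatModel(waves=waves, heart_rate=hr, rr_jitter=template.rr_jitter,
                     edge_fraction=template.edge_fraction)


class EmptyCohortError(ValueError):
    """Raised when a cohort with zero participants is requested."""


def generate_cohort(
    n_participants: int = 36,
    n_sessions: int = 2,
    layout: ProtocolLayout | None = None,
    template: BeatModel | None = None,
    effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    cpt_range_s: tuple[float, float] = (60.0, 120.0),
) -> list[tuple[EcgRecording, GroundTruth]]:
    """Generate ``n_participants x n_sessions`` recordings with ground truth.

    Each participant keeps one beat morphology across sessions; sessions
    differ only through seed-driven jitter, noise and the per-session CPT
    duration (drawn uniformly from ``cpt_range_s``).  Fully reproducible from
    (seed, parameters).
    """
    if n_participants < 1:
        raise EmptyCohortError("cohort needs at least one participant")
    if n_sessions < 1:
        raise EmptyCohortError("cohort needs at least one session")
    layout = layout if layout is not None else ProtocolLayout()
    template = template if template is not None else BeatModel()
    effect = effect if effect is not None else EffectSpec()
    noise = noise if noise is not None else NoiseSpec()

    root = np.random.SeedSequence(seed)
    participant_seqs = root.spawn(n_participants)

    out: list[tuple[EcgRecording, GroundTruth]] = []
    has_cpt = any(lab == "cpt" for lab, _ in layout.epochs)
    for p_idx, p_seq in enumerate(participant_seqs):
        p_rng = np.random.default_rng(p_seq)
        model = _draw_beat_model(p_rng, template)
        session_seqs = p_seq.spawn(n_sessions)
        for s_idx, s_seq in enumerate(session_seqs):
            s_rng = np.random.default_rng(s_seq)
            this_layout = layout
            if has_cpt:
                cpt_s = float(s_rng.uniform(*cpt_range_s))
                this_layout = layout.with_cpt_duration(cpt_s)
            beat_seed, noise_seed = s_rng.integers(0, 2**31 - 1, size=2)
            clean, truth = synth_beat_train(model, this_layout, effect,
                                            seed=int(beat_seed))
            noisy = add_noise(clean, noise, seed=int(noise_seed), fs=this_layout.fs)
            rec = EcgRecording(
                signal=noisy,
                fs=this_layout.fs,
                participant=f"P{p_idx + 1:02d}",
                session=s_idx + 1,
                triggers=this_layout.intervals(),
            )
            out.append((rec, truth))
    return out
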