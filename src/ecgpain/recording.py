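"""Core recording container shared by the generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Protocol epochs in temporal order.
EPOCH_LABELS = ("baseline", "warm1", "cpt", "warm2", "rest")


class AnnotationError(ValueError):
    """Raised when trigger annotations are missing, overlapping or out of bounds."""


@dataclass
class EcgRecording:
    """One channel of ECG with its sampling rate, identity and triggers.

    Parameters
    ----------
    signal
        Sample values in mV.
    fs
        Sampling rate in Hz (> 0).
    participant
        Participant identifier.
    session
        Session number (1 = fear-context CPT, 2 = neutral-context CPT).
    triggers
        Mapping from epoch label to half-open ``[start, end)`` sample interval.
    """

    signal: np.ndarray
    fs: float
    participant: str = "P00"
    session: int = 1
    triggers: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate_triggers(self, required: tuple[str, ...] = EPOCH_LABELS) -> None:
        """Check that the required epochs are present, ordered, disjoint and in bounds."""
        missing = [lab for lab in required if lab not in self.triggers]
        if missing:
            raise AnnotationError(f"missing trigger epochs: {missing}")
        prev_end = 0
        for lab in required:
            start, end = self.triggers[lab]
            if not (0 <= start < end <= self.n_samples):
                raise AnnotationError(
                    f"epoch {lab!r} interval [{start}, {end}) outside signal of "
                    f"length {self.n_samples}"
                )
            if start < prev_end:
                raise AnnotationError(f"epoch {lab!r} overlaps the previous epoch")
            prev_end = end

    def with_signal(self, signal: np.ndarray) -> "EcgRecording":
        """Copy of this recording with the samples replaced (metadata kept)."""
        return EcgRecording(
            signal=signal,
            fs=self.fs,
            participant=self.participant,
            session=self.session,
            triggers=dict(self.triggers),
        )
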