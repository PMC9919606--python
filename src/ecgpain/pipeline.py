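"""High-level stage composition: recording -> fiducials -> labeled features.

Shared by the CLI, the test suite and the acceptance script so every caller
exercises the same path.
"""

from __future__ import annotations

import logging

import pandas as pd

from ecgpain.delineate import DelineationConfig, delineate_waves, detect_r_peaks
from ecgpain.features import (
    assemble_dataset,
    build_feature_table,
    normalize_by_baseline,
)
from ecgpain.preprocess import design_bandpass, preprocess_recording, segment_epochs
from ecgpain.recording import EcgRecording
from ecgpain.synth import GroundTruth, generate_cohort

log = logging.getLogger(__name__)


def recording_features(rec: EcgRecording,
                       delineation: DelineationConfig | None = None,
                       truth: GroundTruth | None = None) -> pd.DataFrame:
    """Filter, delineate and window one recording into its feature rows.

    When ``truth`` is given its fiducials are used instead of running the
    delineator (fast path for calibration studies on synthetic data); the
    signal is still band-pass filtered so amplitude features see the same
    preprocessing either way.
    """
    filtered = preprocess_recording(rec, design_bandpass(fs_hz=rec.fs))
    epoch_map = segment_epochs(rec)
    if truth is not None:
        fiducials = truth
    else:
        r_peaks = detect_r_peaks(filtered.signal, rec.fs)
        fiducials = delineate_waves(filtered.signal, r_peaks, rec.fs, delineation)
        if fiducials.n_dropped:
            log.info("%s s%d: dropped %d beats (%s)", rec.participant,
                     rec.session, fiducials.n_dropped, fiducials.drop_reasons)
    return build_feature_table(
        fiducials, filtered.signal, epoch_map.segments,
        rec.participant, rec.session, rec.fs,
    )


def cohort_dataset(cohort: list[tuple[EcgRecording, GroundTruth]],
                   use_ground_truth: bool = False,
                   delineation: DelineationConfig | None = None) -> pd.DataFrame:
    """Labeled baseline/CPT feature table for a whole cohort."""
    tables = [
        recording_features(rec, delineation, truth if use_ground_truth else None)
        for rec, truth in cohort
    ]
    table = pd.concat(tables, ignore_index=True)
    normalized, _ = normalize_by_baseline(table)
    return assemble_dataset(normalized)


def default_cohort_dataset(seed: int = 0, n_participants: int = 36,
                           n_sessions: int = 2, **cohort_kwargs) -> pd.DataFrame:
    """Generate the default synthetic cohort and run the full pipeline."""
    cohort = generate_cohort(n_participants=n_participants,
                             n_sessions=n_sessions, seed=seed, **cohort_kwargs)
    return cohort_dataset(cohort)
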