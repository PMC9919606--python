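import numpy as np
import pandas as pd
import pytest

from ecgpain.features import FEATURE_COLUMNS
from ecgpain.preprocess import apply_zero_phase, center, design_bandpass
from ecgpain.synth import (
    BeatModel,
    EffectSpec,
    ProtocolLayout,
    synth_beat_train,
)


@pytest.fixture(scope="session")
def clean_train():
    """300 s baseline-only train, 60 bpm, no jitter: signal + ground truth."""
    layout = ProtocolLayout(epochs=(("baseline", 300.0),))
    model = BeatModel(rr_jitter=0.0)
    signal, truth = synth_beat_train(model, layout, EffectSpec.identity(), seed=0)
    return signal, truth, layout


@pytest.fixture(scope="session")
def filtered_clean(clean_train):
    signal, truth, layout = clean_train
    filt = design_bandpass(fs_hz=layout.fs)
    return apply_zero_phase(filt, center(signal)), truth, layout


def synthetic_feature_table(n_participants=6, n_sessions=2, seed=0,
                            effect_size=1.0, n_baseline=20, n_cpt=8):
    """Labeled feature table drawn directly from distributions (no ECG).

    Class separation is injected into S_amplitude only, scaled by
    ``effect_size`` (0 = null).  Useful for testing split/metric logic
    without running the signal pipeline.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for s in range(1, n_sessions + 1):
            for epoch, n, label in (("baseline", n_baseline, 0), ("cpt", n_cpt, 1)):
                for w in range(n):
                    row = {c: rng.normal(1.0, 0.05) for c in FEATURE_COLUMNS}
                    if label:
                        row["S_amplitude"] -= 0.3 * effect_size
                    row.update(participant=f"P{p + 1:02d}", session=s,
                               epoch=epoch, window_start=w * 5000, label=label)
                    rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def small_table():
    return synthetic_feature_table()
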