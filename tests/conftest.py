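import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ppg2ecg as p

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def recall(detected, truth, tol):
    """Fraction of true events matched by a detection within ``tol`` samples."""
    detected = np.asarray(detected)
    if len(detected) == 0 or len(truth) == 0:
        return 0.0
    return sum(1 for t in truth if np.min(np.abs(detected - t)) <= tol) / len(truth)


@pytest.fixture(scope="session")
def clean_record():
    """300 s noise-free synthetic record, 72 bpm, PAT 0.24 s."""
    params = p.SynthParams(
        duration_s=300.0, hr_bpm=72.0, hrv_sd_s=0.03, pat_s=0.24, noise_sd=0.0, seed=11
    )
    return p.gen_record(params)


@pytest.fixture(scope="session")
def noisy_record():
    """300 s record with realistic additive noise."""
    params = p.SynthParams(
        duration_s=300.0, hr_bpm=72.0, hrv_sd_s=0.03, pat_s=0.24, noise_sd=0.02, seed=12
    )
    return p.gen_record(params)


@pytest.fixture()
def cfg():
    return p.RunConfig(seed=7, gap_seconds=2.0)


@pytest.fixture(scope="session")
def tiny_trained():
    """A small but real training run shared by trainer/CLI tests.

    4 records, 60 s each, 10 epochs: enough for the loss to fall and for
    determinism checks, cheap enough for the default test run.
    """
    from ppg2ecg.cli import simulate_records
    from ppg2ecg.preprocess import preprocess_record

    cfg = p.RunConfig(
        seed=3, gap_seconds=1.0, record_seconds_used=45.0, epochs=10, batch_size=16
    )
    records = simulate_records(4, seed=3, duration_s=60.0, noise_sd=0.02)
    train_set, val_set, stores = [], [], {}
    for rec in records:
        segs, (tr, va, te), gap, _ = preprocess_record(rec, cfg)
        train_set.extend(segs[i] for i in tr)
        val_set.extend(segs[i] for i in va)
        stores[rec.record_id] = (segs, (tr, va, te))
    model = p.build_model(p.ModelSpec(variant="wnet", seed=3))
    model, state = p.train(model, train_set, val_set, cfg)
    return model, state, stores, cfg
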