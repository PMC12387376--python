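import numpy as np
import pytest

from respcomplex.synthetic import PhenotypeProfile, simulate_recording


@pytest.fixture
def clean_profile() -> PhenotypeProfile:
    """Deterministic profile: no jitter, noise, drift, modulation or artifacts."""
    return PhenotypeProfile(
        mean_bbi=3.0,
        te_fraction=0.6,
        bbi_jitter_sd=0.0,
        envelope_depth=0.0,
        envelope_phase_jitter=0.0,
        amplitude_noise_sd=0.0,
        amplitude_drift_sd=0.0,
        drift_amplitude=0.0,
        noise_sd=0.0,
        artifact_rate=0.0,
    )


@pytest.fixture
def clean_recording(clean_profile):
    return simulate_recording(clean_profile, 300.0, seed=1)


def brute_force_sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Independent pair-enumeration oracle for SampEn match counts.

    Enumerates all unordered template pairs directly from the definition
    using explicit sliding windows; O(N^2 m).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    a = b = 0
    for i in range(nt - 1):
        db = np.max(np.abs(tm[i + 1 :] - tm[i]), axis=1)
        da = np.max(np.abs(tm1[i + 1 :] - tm1[i]), axis=1)
        b += int((db <= r).sum())
        a += int((da <= r).sum())
    return a, b
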