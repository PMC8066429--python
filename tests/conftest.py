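"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity by exhaustive enumeration
(O(n^2) pair loops, literal re-scans of the burst rule) so they stay
independent of the sort-merge implementations they check.
"""

import numpy as np
import pytest

from vpetypes import SpikeTrain, demo_config, simulate_session


# ---------------------------------------------------------------------------
# oracles

def brute_correlogram_counts(ref_s, target_s, bin_ms, window_ms, auto=False):
    """Exhaustive pair enumeration into half-open bins centered on multiples
    of bin_ms; for auto correlograms the zero-lag bin is cleared."""
    n_half = int(round(window_ms / bin_ms))
    counts = np.zeros(2 * n_half + 1)
    for r in np.asarray(ref_s, dtype=float):
        for t in np.asarray(target_s, dtype=float):
            k = int(np.floor((t - r) * 1000.0 / bin_ms + 0.5))
            if -n_half <= k <= n_half:
                counts[k + n_half] += 1
    if auto:
        counts[n_half] = 0
    return counts


def brute_correlogram_counts_outer(ref_s, target_s, bin_ms, window_ms, auto=False):
    """Same exhaustive enumeration as brute_correlogram_counts, via a full
    O(n^2) outer-difference matrix (fast enough for 1000-train sweeps while
    staying independent of the sort-merge implementation)."""
    ref = np.asarray(ref_s, dtype=float)
    tgt = np.asarray(target_s, dtype=float)
    n_half = int(round(window_ms / bin_ms))
    if len(ref) == 0 or len(tgt) == 0:
        return np.zeros(2 * n_half + 1)
    d = np.subtract.outer(tgt, ref).ravel()
    k = np.floor(d * 1000.0 / bin_ms + 0.5).astype(np.int64) + n_half
    k = k[(k >= 0) & (k < 2 * n_half + 1)]
    counts = np.bincount(k, minlength=2 * n_half + 1).astype(float)
    if auto:
        counts[n_half] = 0
    return counts


def brute_parse_labels(times_s, first_max_ms=10.0, intra_max_ms=15.0):
    """Literal re-scan of the burst rule, spike by spike."""
    t = np.asarray(times_s, dtype=float)
    n = len(t)
    labels = ["single"] * n
    i = 0
    while i < n - 1:
        isi = (t[i + 1] - t[i]) * 1000.0
        if isi < first_max_ms:
            labels[i] = "burst_first"
            j = i + 1
            labels[j] = "burst_member"
            while j + 1 < n and (t[j + 1] - t[j]) * 1000.0 < intra_max_ms:
                j += 1
                labels[j] = "burst_member"
            i = j + 1
        else:
            i += 1
    return labels


def poisson_train(rate_hz, duration_s, rng):
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, n))


def random_train(rng, max_spikes=200, duration_s=1.0):
    """Random sorted train with a spread of densities, some ISIs in the
    burst range."""
    n = int(rng.integers(0, max_spikes + 1))
    t = np.sort(rng.uniform(0.0, duration_s, n))
    return np.unique(t)


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_session():
    """Small synthetic session reused by session/pipeline tests."""
    cfg = demo_config(seed=11, n_trials=60)
    session, gt = simulate_session(cfg)
    return session, gt, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def as_train(times, unit_id="u"):
    return SpikeTrain(unit_id=unit_id, times=np.asarray(times, dtype=float))
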