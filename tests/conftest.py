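import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230536)


def direct_dft_coherence(x, y, fs, band, window_len=10.0, overlap=0.5):
    """Independent direct-definition Welch coherence oracle.

    Explicit per-window DFT via the definition sum, explicit averaging of
    cross- and auto-spectra, band mean over rfft bins — no shared code
    with the estimator under test.
    """
    n = int(round(window_len * fs))
    step = n - int(round(n * overlap))
    k = np.arange(n)
    hann = 0.5 - 0.5 * np.cos(2 * np.pi * k / n)  # periodic Hann
    n_freq = n // 2 + 1
    dft = np.exp(-2j * np.pi * np.outer(np.arange(n_freq), k) / n)
    sxx = np.zeros(n_freq)
    syy = np.zeros(n_freq)
    sxy = np.zeros(n_freq, dtype=complex)
    count = 0
    for start in range(0, len(x) - n + 1, step):
        fx = dft @ (hann * x[start : start + n])
        fy = dft @ (hann * y[start : start + n])
        sxx += np.abs(fx) ** 2
        syy += np.abs(fy) ** 2
        sxy += fx * np.conj(fy)
        count += 1
    assert count >= 2
    sxx /= count
    syy /= count
    sxy /= count
    freqs = np.arange(n_freq) * fs / n
    coh = np.abs(sxy) ** 2 / (sxx * syy)
    sel = (freqs >= band.lo) & (freqs <= band.hi)
    return float(coh[sel].mean())


def brute_force_holm(p):
    """Holm adjustment straight from the step-down definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, i in enumerate(order):
        running_max = max(running_max, (m - rank) * p[i])
        adjusted[i] = min(running_max, 1.0)
    return adjusted
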