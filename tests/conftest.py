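"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import settings

from fetalstress.fsi_core import FSIConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> FSIConfig:
    return FSIConfig()


def tone_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Exact-frequency amplitude via least squares on sin/cos regressors.

    Unlike a raw FFT bin this is unbiased for tones whose period does not
    divide the record length, so it serves as the oracle for amplitude
    recovery checks.
    """
    t = np.arange(len(x)) / fs
    design = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t), np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def fft_peak_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Hann-windowed FFT amplitude at the bin nearest ``freq``."""
    w = np.hanning(len(x))
    spec = np.abs(np.fft.rfft((x - x.mean()) * w))
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return float(2.0 * spec[np.argmin(np.abs(freqs - freq))] / w.sum())


def ranksum_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group labels.

    Independent brute-force oracle: enumerates every C(m+n, m) assignment
    of the pooled observations to the first group and counts U statistics
    at least as extreme (two-sided, exploiting the symmetry of the null
    distribution of U about mn/2).
    """
    pooled = np.concatenate([x, y])
    m, n = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # tie-free by construction
    u_obs = np.sum(ranks[:m]) - m * (m + 1) / 2.0
    u_extreme = max(u_obs, m * n - u_obs)
    count = 0
    total = 0
    for idx in combinations(range(m + n), m):
        u = np.sum(ranks[list(idx)]) - m * (m + 1) / 2.0
        if max(u, m * n - u) >= u_extreme - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_enumeration_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(rho, two-sided exact p) by enumerating all pairings of y against x."""
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0
    n = len(x)

    def rho_of(r1: np.ndarray, r2: np.ndarray) -> float:
        return float(np.corrcoef(r1, r2)[0, 1])

    rho_obs = rho_of(rx, ry)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = rho_of(rx, ry[list(perm)])
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return rho_obs, count / total
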