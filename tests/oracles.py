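"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, direct enumeration)
kept separate from the package code paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_clustering(w: np.ndarray) -> float:
    """Global weighted clustering by explicit triangle enumeration."""
    n = w.shape[0]
    per_node = []
    for i in range(n):
        neigh = [j for j in range(n) if j != i and w[i, j] > 0]
        k = len(neigh)
        if k < 2:
            per_node.append(0.0)
            continue
        total = 0.0
        for a in range(len(neigh)):
            for b in range(a + 1, len(neigh)):
                j, h = neigh[a], neigh[b]
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        per_node.append(2.0 * total / (k * (k - 1)))
    return float(np.mean(per_node))


def brute_path_length(w: np.ndarray) -> float:
    """Characteristic path length via hand-written Floyd-Warshall."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if i != j and w[i, j] > 0:
                dist[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    off = [dist[i, j] for i in range(n) for j in range(n) if i != j]
    return float(np.mean(off))


def brute_icc(values: np.ndarray) -> tuple[float, float, float, float]:
    """Single-rating absolute-agreement ICC by cell-level SS enumeration.

    Returns (icc, MSR, MSC, MSE); intentionally loop-based.
    """
    n, k = values.shape
    grand = sum(values[i, j] for i in range(n) for j in range(k)) / (n * k)
    rows = [sum(values[i, j] for j in range(k)) / k for i in range(n)]
    cols = [sum(values[i, j] for i in range(n)) / n for j in range(k)]
    ssr = sum(k * (rows[i] - grand) ** 2 for i in range(n))
    ssc = sum(n * (cols[j] - grand) ** 2 for j in range(k))
    sse = sum(
        (values[i, j] - rows[i] - cols[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return icc, msr, msc, mse


def brute_rm_anova(y: np.ndarray) -> dict[str, tuple[float, float]]:
    """2x2 within-subject ANOVA sums of squares by direct enumeration.

    Returns {effect: (ss_effect, ss_error)} for the two main effects and
    the interaction, each with its subject-by-effect error term.
    """
    n = y.shape[0]
    g = y.mean()
    subj = [y[i].mean() for i in range(n)]
    A = [y[:, a, :].mean() for a in range(2)]
    B = [y[:, :, b].mean() for b in range(2)]
    AB = [[y[:, a, b].mean() for b in range(2)] for a in range(2)]
    SA = [[y[i, a, :].mean() for a in range(2)] for i in range(n)]
    SB = [[y[i, :, b].mean() for b in range(2)] for i in range(n)]

    ss_a = sum(2 * n * (A[a] - g) ** 2 for a in range(2))
    ss_b = sum(2 * n * (B[b] - g) ** 2 for b in range(2))
    ss_ab = sum(n * (AB[a][b] - A[a] - B[b] + g) ** 2
                for a in range(2) for b in range(2))
    ss_as = sum(2 * (SA[i][a] - subj[i] - A[a] + g) ** 2
                for i in range(n) for a in range(2))
    ss_bs = sum(2 * (SB[i][b] - subj[i] - B[b] + g) ** 2
                for i in range(n) for b in range(2))
    ss_abs = sum(
        (y[i, a, b] - SA[i][a] - SB[i][b] - AB[a][b]
         + subj[i] + A[a] + B[b] - g) ** 2
        for i in range(n) for a in range(2) for b in range(2)
    )
    return {"exercise": (ss_a, ss_as), "session": (ss_b, ss_bs),
            "interaction": (ss_ab, ss_abs)}


def hand_unrolled_connectivity(
    epoch: np.ndarray, fs: float, nper: int, band_lo: float, band_hi: float
) -> tuple[float, float]:
    """wPLI and magnitude coherence of channels (0, 1) by direct unrolling.

    Hann-tapered 50%-overlap segments, explicit per-bin ratios, mean over
    bins with centre in [band_lo, band_hi).
    """
    n_t = epoch.shape[1]
    step = nper // 2
    starts = list(range(0, n_t - nper + 1, step))
    # periodic (DFT-even) Hann taper
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nper) / nper)
    X, Y = [], []
    for s in starts:
        X.append(np.fft.rfft(epoch[0, s:s + nper] * win))
        Y.append(np.fft.rfft(epoch[1, s:s + nper] * win))
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    bins = [b for b, f in enumerate(freqs) if band_lo <= f < band_hi]
    wpli_bins, coh_bins = [], []
    for b in bins:
        sxy = [X[s][b] * np.conj(Y[s][b]) for s in range(len(starts))]
        imag = [v.imag for v in sxy]
        den = sum(abs(v) for v in imag)
        wpli_bins.append(abs(sum(imag)) / den if den > 0 else 0.0)
        sxx = np.mean([abs(X[s][b]) ** 2 for s in range(len(starts))])
        syy = np.mean([abs(Y[s][b]) ** 2 for s in range(len(starts))])
        coh_bins.append(abs(np.mean(sxy)) / np.sqrt(sxx * syy))
    return float(np.mean(wpli_bins)), float(np.mean(coh_bins))
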