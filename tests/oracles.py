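"""Independent explicit-loop reference implementations.

Everything here is written with plain Python loops and scalar math so it
shares no code path with the package's vectorized implementations; tests
compare the two routes on randomized inputs.
"""

from __future__ import annotations

import math


def disten_oracle(series, m: int = 3, tau: int = 1, bins: int = 256, all_vectors: bool = False):
    """Distribution entropy by full enumeration of the distance matrix."""
    x = [float(v) for v in series]
    n = len(x)
    n_vectors = n - m * tau + (1 if all_vectors else 0)
    assert n_vectors >= 2, "series too short"
    vectors = []
    for i in range(n_vectors):
        vectors.append([x[i + k * tau] for k in range(m)])

    distances = []
    for i in range(n_vectors):
        for j in range(n_vectors):
            if i == j:
                continue
            d = 0.0
            for k in range(m):
                diff = abs(vectors[i][k] - vectors[j][k])
                if diff > d:
                    d = diff
            distances.append(d)

    dmin = min(distances)
    dmax = max(distances)
    counts = [0] * bins
    if dmax == dmin:
        counts[0] = len(distances)
    else:
        scale = bins / (dmax - dmin)
        for d in distances:
            idx = int(math.floor((d - dmin) * scale))
            if idx < 0:
                idx = 0
            if idx > bins - 1:
                idx = bins - 1
            counts[idx] += 1

    total = len(distances)
    entropy = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            entropy += p * math.log2(p)
    return -entropy / math.log2(bins)


def distance_probs_oracle(series, m: int, tau: int, bins: int):
    """Binned distance probabilities by the same full enumeration."""
    x = [float(v) for v in series]
    n = len(x)
    n_vectors = n - m * tau
    vectors = [[x[i + k * tau] for k in range(m)] for i in range(n_vectors)]
    distances = []
    for i in range(n_vectors):
        for j in range(n_vectors):
            if i != j:
                distances.append(max(abs(a - b) for a, b in zip(vectors[i], vectors[j])))
    dmin, dmax = min(distances), max(distances)
    counts = [0] * bins
    if dmax == dmin:
        counts[0] = len(distances)
    else:
        scale = bins / (dmax - dmin)
        for d in distances:
            counts[min(max(int(math.floor((d - dmin) * scale)), 0), bins - 1)] += 1
    return [c / len(distances) for c in counts]


def rmssd_oracle(series):
    total = 0.0
    n = 0
    for a, b in zip(series[:-1], series[1:]):
        total += (float(b) - float(a)) ** 2
        n += 1
    return math.sqrt(total / n)


def sdnn_oracle(series):
    vals = [float(v) for v in series]
    mean = sum(vals) / len(vals)
    return math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))


def pnnx_oracle(series, x: float):
    count = 0
    n = 0
    for a, b in zip(series[:-1], series[1:]):
        if abs(float(b) - float(a)) > x:
            count += 1
        n += 1
    return 100.0 * count / n


def noise_score_oracle(series, window: int = 3):
    """Two-pass SD of moving within-window SDs, explicit loops throughout."""
    vals = [float(v) for v in series]
    moving = []
    for start in range(len(vals) - window + 1):
        w = vals[start : start + window]
        mean = sum(w) / window
        moving.append(math.sqrt(sum((v - mean) ** 2 for v in w) / (window - 1)))
    mean_m = sum(moving) / len(moving)
    return math.sqrt(sum((v - mean_m) ** 2 for v in moving) / (len(moving) - 1))
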