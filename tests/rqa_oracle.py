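"""Independent brute-force RQA reference used only by the tests.

Plain-Python O(N^2) pairwise checks and an explicit diagonal-walking
line histogram, deliberately sharing no code with the package.
"""

import math

import numpy as np


def brute_embed(series, m, tau):
    n = len(series) - (m - 1) * tau
    return [[series[i + j * tau] for j in range(m)] for i in range(n)]


def brute_matrix(states, eps_abs, norm="euclidean"):
    n = len(states)
    r = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if norm == "maximum":
                d = max(abs(a - b) for a, b in zip(states[i], states[j]))
            else:
                d = math.sqrt(sum((a - b) ** 2 for a, b in zip(states[i], states[j])))
            r[i, j] = d <= eps_abs
    return r


def brute_diameter(states, norm="euclidean"):
    best = 0.0
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            if norm == "maximum":
                d = max(abs(a - b) for a, b in zip(states[i], states[j]))
            else:
                d = math.sqrt(sum((a - b) ** 2 for a, b in zip(states[i], states[j])))
            best = max(best, d)
    return best


def brute_rec(r, theiler=0):
    n = r.shape[0]
    hits = admissible = 0
    for i in range(n):
        for j in range(n):
            if abs(i - j) > theiler:
                admissible += 1
                if r[i, j]:
                    hits += 1
    return hits / admissible


def brute_det(r, l_min=2, theiler=0):
    n = r.shape[0]
    total = 0
    on_lines = 0
    for k in range(-(n - 1), n):
        if abs(k) <= theiler:
            continue
        run = 0
        cells = [(i, i + k) for i in range(n) if 0 <= i + k < n]
        for i, j in cells + [(-1, -1)]:  # sentinel terminates the last run
            if i >= 0 and r[i, j]:
                run += 1
                total += 1
            else:
                if run >= l_min:
                    on_lines += run
                run = 0
    if total == 0:
        return float("nan")
    return on_lines / total
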