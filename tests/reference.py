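"""Independent brute-force reference implementations used as oracles.

Everything here is written in plain Python loops, straight from the
contract: no numpy vectorization, no caching, no reuse of the package's
internals.  Deliberately slow and simple.
"""

import math


def ref_direction(point, origin):
    v = [point[0] - origin[0], point[1] - origin[1], point[2] - origin[2]]
    n = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if n == 0.0:
        raise ValueError("zero-length direction")
    return [v[0] / n, v[1] / n, v[2] / n]


def ref_dispersion_deg(points, origin):
    """Max pairwise angle (degrees) by double loop over all pairs."""
    dirs = [ref_direction(p, origin) for p in points]
    worst = 0.0
    for a in range(len(dirs)):
        for b in range(a + 1, len(dirs)):
            c = sum(dirs[a][k] * dirs[b][k] for k in range(3))
            c = max(-1.0, min(1.0, c))
            ang = math.degrees(math.acos(c))
            if ang > worst:
                worst = ang
    return worst


def ref_head_mean(heads):
    n = len(heads)
    out = [0.0, 0.0, 0.0]
    for h in heads:
        for k in range(3):
            out[k] += h[k]
    return [out[k] / n for k in range(3)]


def ref_detect(t, gaze, head, dispersion_th, time_window, freq_floor):
    """Sliding-window I-DT re-implemented directly from the contract.

    Returns the list of (start, stop) half-open member index ranges.
    Dispersion is recomputed from scratch (double loop) at every step, with
    the head origin re-averaged over the current members.
    """
    n = len(t)
    max_gap = 1.0 / freq_floor
    out = []
    i = 0
    while i < n:
        j = i
        while j < n and t[j] - t[i] < time_window:
            j += 1
        if j >= n:
            break
        ok = all(t[k + 1] - t[k] <= max_gap for k in range(i, j))
        if ok:
            hm = ref_head_mean(head[i : j + 1])
            ok = ref_dispersion_deg(gaze[i : j + 1], hm) <= dispersion_th
        if not ok:
            i += 1
            continue
        k = j
        while k + 1 < n:
            if t[k + 1] - t[k] > max_gap:
                break
            hm = ref_head_mean(head[i : k + 2])
            if ref_dispersion_deg(gaze[i : k + 2], hm) > dispersion_th:
                break
            k += 1
        out.append((i, k + 1))
        i = k + 1
    return out


def ref_sma3(x):
    out = []
    n = len(x)
    if n <= 2:
        return list(x)
    for i in range(n):
        lo = max(0, i - 1)
        hi = min(n, i + 2)
        out.append(sum(x[lo:hi]) / (hi - lo))
    return out
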