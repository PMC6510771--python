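"""Independent brute-force reference for the deviation indices.

Deliberately written with a different formulation than the package: complex
rotation instead of cross/dot products, explicit per-step Python loops, and
its own truncation logic.  Used only to check the vectorised implementation.
"""

import cmath
import math


def oracle_indices(t, xy, platform_center, platform_radius, max_trial_s):
    """Per-trial sums of the four deviation indices, one step at a time.

    ``t``/``xy`` must already be on the analysis grid.  Returns a dict with
    the four sums, the escape latency, and the number of steps covered.
    """
    b = complex(platform_center[0], platform_center[1])
    pts = [complex(x, y) for x, y in xy]

    stop = None
    for i, p in enumerate(pts):
        if t[i] > max_trial_s + 1e-9:
            stop = i  # exclusive: previous sample was the last inside the cap
            break
        if abs(p - b) <= platform_radius:
            stop = i + 1
            break
    if stop is None:
        stop = len(pts)
    pts = pts[:stop]
    escaped = abs(pts[-1] - b) <= platform_radius
    latency = t[stop - 1] if escaped else max_trial_s

    c0 = pts[0]
    u0 = (b - c0) / abs(b - c0)
    index1 = index2 = index3 = index4 = 0.0
    for c_n, c_next in zip(pts[:-1], pts[1:]):
        z = c_next - c_n
        route = b - c_n
        index4 += abs((z / u0).imag)
        if abs(z) == 0.0 or abs(route) == 0.0:
            continue  # stationary or on the platform centre: no deviation
        rel = z / (route / abs(route))
        index1 += abs(rel.imag)
        theta = abs(cmath.phase(rel))
        index2 += math.degrees(theta)
        index3 += 2.0 * abs(z) * math.sin(theta / 2.0)
    return {
        "index1_cm": index1,
        "index2_deg": index2,
        "index3_cm": index3,
        "index4_cm": index4,
        "escape_latency_s": latency,
        "escaped": escaped,
        "n_steps": len(pts) - 1,
    }


def oracle_auc(pos, neg):
    """AUC by exhaustive pair enumeration; ties count one half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
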