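"""Independent brute-force oracles used by several test modules.

These deliberately avoid the package's own code paths (and numpy/scipy
shortcuts) so they can serve as arithmetic cross-checks.
"""

import math


def brute_force_ks_phard(ci, ri):
    """KS-based probability of hardness via explicit loops and the
    Kolmogorov series (independent of the package implementation)."""
    shift = min(min(ci), min(ri))
    a = [v - shift for v in ci]
    b = [v - shift for v in ri]
    fa = [sum(a[: k + 1]) / sum(a) for k in range(len(a))]
    fb = [sum(b[: k + 1]) / sum(b) for k in range(len(b))]
    d = max(abs(x - y) for x, y in zip(fa, fb))
    x = math.sqrt(len(ci) / 2.0) * d
    if x < 1e-12:
        return 1.0
    return max(
        0.0,
        min(
            1.0,
            2.0
            * sum((-1) ** (k - 1) * math.exp(-2 * k * k * x * x) for k in range(1, 101)),
        ),
    )


def hand_stats(m):
    """Overall accuracy (%) and Cohen's kappa by explicit hand arithmetic."""
    m = [list(map(float, row)) for row in m]
    k = len(m)
    total = sum(sum(r) for r in m)
    diag = sum(m[i][i] for i in range(k))
    overall = 100.0 * diag / total
    rows = [sum(m[i]) for i in range(k)]
    cols = [sum(m[i][j] for i in range(k)) for j in range(k)]
    po = diag / total
    pe = sum(rows[i] * cols[i] for i in range(k)) / total**2
    kappa = float("nan") if abs(1 - pe) < 1e-15 else (po - pe) / (1 - pe)
    return overall, kappa
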