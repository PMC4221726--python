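"""Independent brute-force oracles for the filter and NMS implementations.

These deliberately use naive explicit loops (per line, per band position,
per band sample; per pixel, per window neighbor) so they share no code
path with the vectorized implementations they check.
"""

import math

import numpy as np


def band_filter_brute(grad, center, params, kind):
    """Triple-loop sliding-band response (SBF or TSBF) at one center."""
    H, W = grad.gx.shape
    total = 0.0
    for i in range(params.n_lines):
        phi = 2 * np.pi * i / params.n_lines
        best = None
        for r in range(params.r_min, params.r_max + 1):
            ssum, cnt = 0.0, 0
            first = r - params.band_width // 2
            for rad in range(first, first + params.band_width):
                if rad < 1:
                    continue
                dr = int(np.round(rad * np.sin(phi)))
                dc = int(np.round(rad * np.cos(phi)))
                rr, cc = center[0] + dr, center[1] + dc
                if not (0 <= rr < H and 0 <= cc < W):
                    continue
                gx, gy = grad.gx[rr, cc], grad.gy[rr, cc]
                norm = math.hypot(dr, dc)
                ur, uc = -dr / norm, -dc / norm
                mag = math.hypot(gx, gy)
                cos = (gx * uc + gy * ur) / mag if mag > 0 else 0.0
                ssum += params.omega * abs(cos) * mag if kind == "TSBF" else cos
                cnt += 1
            if cnt:
                m = ssum / cnt
                best = m if best is None else max(best, m)
        total += best if best is not None else 0.0
    return total / params.n_lines


def nms_brute(values, half, threshold):
    """Direct O(W*H*n^2) scan implementing the NMS contract.

    Keep (r, c) iff value > threshold, value >= all window values, and no
    equal-valued pixel with lexicographically smaller index in the window.
    """
    H, W = values.shape
    keep = []
    for r in range(H):
        for c in range(W):
            v = values[r, c]
            if not v > threshold:
                continue
            ok = True
            for rr in range(max(0, r - half), min(H, r + half + 1)):
                for cc in range(max(0, c - half), min(W, c + half + 1)):
                    if values[rr, cc] > v:
                        ok = False
                    elif values[rr, cc] == v and (rr, cc) < (r, c):
                        ok = False
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                keep.append((r, c))
    return keep
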