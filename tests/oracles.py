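"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by direct enumeration or summation,
deliberately sharing no code with the library path it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- candidates
def naive_local_maxima(y):
    """Plateau-aware local maxima of a 1D array: indices of plateau centers."""
    n = len(y)
    out = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def naive_prominence(y, p):
    """Prominence by exhaustive valley search to the nearest higher ground."""
    bases = []
    for step in (-1, 1):
        i = p + step
        low = y[p]
        while 0 <= i < len(y) and y[i] <= y[p]:
            low = min(low, y[i])
            i += step
        bases.append(low)
    return y[p] - max(bases)


def naive_candidates(y, mask, positions, min_separation, min_prominence):
    """O(n^2) candidate detection on an intensity array.

    Local maxima are found per unmasked run; every candidate is tested
    against all others within ``min_separation`` and removed if any of them
    is higher (ties: the leftmost wins).
    """
    raw = []
    n = len(y)
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        seg = y[i:j]
        for p in naive_local_maxima(seg):
            if naive_prominence(seg, p) >= min_prominence:
                raw.append(i + p)
        i = j
    kept = []
    for p in raw:
        dominated = False
        for q in raw:
            if q == p or abs(positions[q] - positions[p]) >= min_separation:
                continue
            if y[q] > y[p] or (y[q] == y[p] and positions[q] < positions[p]):
                dominated = True
                break
        if not dominated:
            kept.append(p)
    return kept


# ------------------------------------------------------------------- extents
def naive_extent(y, mask, peak, avg_ipf):
    """Sample-by-sample half-max walk (half-open index interval)."""
    level = avg_ipf + (y[peak] - avg_ipf) / 2.0
    i0 = peak
    while i0 - 1 >= 0 and not mask[i0 - 1] and y[i0 - 1] > level:
        i0 -= 1
    i1 = peak + 1
    while i1 < len(y) and not mask[i1] and y[i1] > level:
        i1 += 1
    return i0, i1


def naive_extents_disjoint(y, mask, peaks, avg_ipf):
    exts = [naive_extent(y, mask, p, avg_ipf) for p in peaks]
    for k in range(1, len(exts)):
        (a0, a1), (b0, b1) = exts[k - 1], exts[k]
        if b0 < a1:
            lo, hi = peaks[k - 1], peaks[k]
            if hi > lo + 1:
                m = lo + 1 + int(np.argmin(y[lo + 1 : hi]))
            else:
                m = hi
            exts[k - 1] = (a0, m)
            exts[k] = (m, b1)
    return exts


# ----------------------------------------------------- punctum set selection
def _ipf_for_subset(y, mask, peaks, tol=1e-12, max_iter=100):
    """Average IPF implied by a fixed punctum subset (extent/baseline fixed point)."""
    avg = float(y[~mask].mean())
    for _ in range(max_iter):
        exts = naive_extents_disjoint(y, mask, peaks, avg)
        punctal = np.zeros(len(y), dtype=bool)
        for i0, i1 in exts:
            punctal[i0:i1] = True
        outside = ~mask & ~punctal
        if not outside.any():
            return float("nan"), exts
        new = float(y[outside].mean())
        if abs(new - avg) <= tol * max(1.0, abs(avg)):
            return new, exts
        avg = new
    return avg, exts


def self_consistent_subsets(y, mask, candidate_peaks, threshold):
    """All candidate subsets whose members each satisfy the ratio rule
    against the inter-punctal baseline that subset itself implies."""
    result = []
    for r in range(len(candidate_peaks) + 1):
        for combo in itertools.combinations(range(len(candidate_peaks)), r):
            peaks = [candidate_peaks[i] for i in combo]
            avg, _ = _ipf_for_subset(y, mask, peaks)
            if not peaks:
                result.append((combo, avg))
                continue
            if not math.isfinite(avg):
                continue
            if all(y[p] / avg >= threshold for p in peaks):
                result.append((combo, avg))
    return result


def maximal_self_consistent_subset(y, mask, candidate_peaks, threshold):
    subsets = self_consistent_subsets(y, mask, candidate_peaks, threshold)
    best = max(subsets, key=lambda t: len(t[0]))
    same_size = [s for s, _ in subsets if len(s) == len(best[0])]
    assert len(same_size) == 1, f"ambiguous maximal subset: {same_size}"
    return best


# ------------------------------------------------------------------------ SE
def direct_se(y, mask, extents, window_lo, window_hi, positions):
    """Recompute total PF / total IPF by explicit masking and math.fsum."""
    punctal = np.zeros(len(y), dtype=bool)
    for i0, i1 in extents:
        punctal[i0:i1] = True
    pf = ipf = 0.0
    pf_terms, ipf_terms = [], []
    for i in range(len(y)):
        if mask[i] or not (window_lo <= positions[i] <= window_hi):
            continue
        (pf_terms if punctal[i] else ipf_terms).append(y[i])
    pf = math.fsum(pf_terms)
    ipf = math.fsum(ipf_terms)
    return pf, ipf


# ------------------------------------------------------- profile extraction
def dense_resample_profile(image, vertices, pixel_size_um, half_width_px, step=0.01):
    """Brute-force line-scan oracle: walk the polyline in 0.01-px arc steps,
    bilinearly interpolating each perpendicular sample point separately."""

    def bilinear(img, x, y):
        x0, y0 = int(np.floor(x)), int(np.floor(y))
        x0 = min(max(x0, 0), img.shape[1] - 2) if img.shape[1] > 1 else 0
        y0 = min(max(y0, 0), img.shape[0] - 2) if img.shape[0] > 1 else 0
        fx, fy = x - x0, y - y0
        return (
            img[y0, x0] * (1 - fx) * (1 - fy)
            + img[y0, x0 + 1] * fx * (1 - fy)
            + img[y0 + 1, x0] * (1 - fx) * fy
            + img[y0 + 1, x0 + 1] * fx * fy
        )

    verts = np.asarray(vertices, dtype=float)
    seg_vecs = np.diff(verts, axis=0)
    seg_len = np.hypot(seg_vecs[:, 0], seg_vecs[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    # dense arc-length table
    s_dense = np.arange(0.0, total + step / 2, step)
    pts = np.empty((s_dense.size, 2))
    tans = np.empty((s_dense.size, 2))
    for k, s in enumerate(s_dense):
        i = min(np.searchsorted(cum, s, side="right") - 1, len(seg_len) - 1)
        f = (s - cum[i]) / seg_len[i]
        pts[k] = verts[i] + f * seg_vecs[i]
        tans[k] = seg_vecs[i] / seg_len[i]

    out = []
    rows, cols = image.shape
    for s in range(int(np.floor(total)) + 1):
        k = int(np.argmin(np.abs(s_dense - s)))
        (x, y), (tx, ty) = pts[k], tans[k]
        nx, ny = -ty, tx
        vals = []
        for off in range(-half_width_px, half_width_px + 1):
            sx, sy = x + off * nx, y + off * ny
            if 0 <= sx <= cols - 1 and 0 <= sy <= rows - 1:
                vals.append(bilinear(image, sx, sy))
        out.append(max(vals) if vals else np.nan)
    return np.asarray(out)
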