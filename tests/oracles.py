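"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately coded with explicit Python loops and literal
formulas, sharing no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(levels, direction, d=1, symmetric=True, ng=None):
    """Double-loop ordered-pair enumeration; level 0 = masked out."""
    levels = np.asarray(levels)
    ng = ng or int(levels.max())
    h, w = levels.shape
    dr, dc = OFFSETS[direction]
    dr, dc = dr * d, dc * d
    counts = np.zeros((ng, ng), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            a, b = levels[r, c], levels[r2, c2]
            if a == 0 or b == 0:
                continue
            counts[a - 1, b - 1] += 1
            if symmetric:
                counts[b - 1, a - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pair")
    return counts / total


def _xlogx(p):
    return p * math.log(p) if p > 0 else 0.0


def haralick_literal(P):
    """Literal-formula evaluation of every scalar GLCM feature."""
    P = np.asarray(P, dtype=float)
    ng = P.shape[0]
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i][j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))
    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + P[i][j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + P[i][j]

    out = {}
    out["glcm_autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i][j] for i in range(ng) for j in range(ng)
    )
    out["glcm_contrast"] = sum(
        (i - j) ** 2 * P[i][j] for i in range(ng) for j in range(ng)
    )
    if sigx > 0 and sigy > 0:
        out["glcm_correlation"] = sum(
            ((i + 1 - mux) / sigx) * ((j + 1 - muy) / sigy) * P[i][j]
            for i in range(ng)
            for j in range(ng)
        )
    else:
        out["glcm_correlation"] = float("nan")
    out["glcm_cluster_shade"] = sum(
        (i + j + 2 - mux - muy) ** 3 * P[i][j] for i in range(ng) for j in range(ng)
    )
    out["glcm_cluster_prominence"] = sum(
        (i + j + 2 - mux - muy) ** 4 * P[i][j] for i in range(ng) for j in range(ng)
    )
    out["glcm_dissimilarity"] = sum(
        abs(i - j) * P[i][j] for i in range(ng) for j in range(ng)
    )
    out["glcm_homogeneity"] = sum(
        P[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    mu_d = sum(k * v for k, v in pdiff.items())
    out["glcm_difference_variance"] = sum(
        (k - mu_d) ** 2 * v for k, v in pdiff.items()
    )
    out["glcm_difference_entropy"] = -sum(_xlogx(v) for v in pdiff.values())
    out["glcm_entropy"] = -sum(
        _xlogx(P[i][j]) for i in range(ng) for j in range(ng)
    )
    out["glcm_energy"] = sum(P[i][j] ** 2 for i in range(ng) for j in range(ng))
    sa = sum(k * v for k, v in psum.items())
    out["glcm_sum_average"] = sa
    out["glcm_sum_entropy"] = -sum(_xlogx(v) for v in psum.values())
    out["glcm_sum_variance"] = sum((k - sa) ** 2 * v for k, v in psum.items())
    out["glcm_maximum_probability"] = max(
        P[i][j] for i in range(ng) for j in range(ng)
    )
    out["glcm_inverse_difference"] = sum(
        P[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    hx = -sum(_xlogx(p) for p in px)
    hy = -sum(_xlogx(p) for p in py)
    hxy = out["glcm_entropy"]
    hxy1 = -sum(
        P[i][j] * math.log(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i][j] > 0
    )
    hxy2 = -sum(
        _xlogx(px[i] * py[j]) for i in range(ng) for j in range(ng)
    )
    denom = max(hx, hy)
    out["glcm_imc1"] = (hxy - hxy1) / denom if denom > 0 else float("nan")
    out["glcm_imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["glcm_idn"] = sum(
        P[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["glcm_idmn"] = sum(
        P[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    return out


def median_bruteforce(arr, kernel):
    """Per-pixel sort-and-middle with reflected borders."""
    arr = np.asarray(arr)
    pad = kernel // 2
    padded = np.pad(arr, pad, mode="symmetric")  # edge-inclusive reflection
    out = np.empty_like(arr)
    h, w = arr.shape
    for r in range(h):
        for c in range(w):
            window = sorted(padded[r : r + kernel, c : c + kernel].ravel())
            out[r, c] = window[len(window) // 2]
    return out


def auc_mannwhitney(scores, labels, positive="case"):
    """Tie-corrected Mann-Whitney AUC by exhaustive pair enumeration.

    Returns the orientation-free AUC max(U, 1-U)/(n1 n2): the larger of
    'higher score favours positive' and its reverse.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    u = total / (len(pos) * len(neg))
    return max(u, 1.0 - u)


def youden_exhaustive(scores, labels, positive="case"):
    """Best J over every candidate threshold and both orientations."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    uniq = np.unique(scores)
    candidates = [-math.inf, math.inf]
    candidates += list(uniq)
    candidates += list((uniq[:-1] + uniq[1:]) / 2.0)
    best_j = -2.0
    for t in candidates:
        for orient in ("le", "gt"):
            called = scores <= t if orient == "le" else scores > t
            sens = np.sum(called & pos) / pos.sum()
            spec = np.sum(~called & ~pos) / (~pos).sum()
            best_j = max(best_j, sens + spec - 1.0)
    return best_j
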