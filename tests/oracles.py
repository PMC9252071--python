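"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops / direct enumeration so it shares
no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- thresholding ----------------------------------------------------------

def otsu_criteria(counts: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Between-class variance at every bin split, by per-split loops."""
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    crits = np.full(len(counts) - 1, -math.inf)
    for k in range(len(counts) - 1):
        w0 = counts[: k + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / counts[: k + 1].sum()
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / counts[k + 1 :].sum()
        crits[k] = w0 * w1 * (mu0 - mu1) ** 2
    return crits


def kapur_criteria(counts: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Kapur entropy sum at every bin split, by per-split loops."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    crits = np.full(len(counts) - 1, -math.inf)

    def entropy(probs):
        q = probs[probs > 0] / probs.sum()
        return float(-(q * np.log(q)).sum())

    for k in range(len(counts) - 1):
        if p[: k + 1].sum() == 0 or p[k + 1 :].sum() == 0:
            continue
        crits[k] = entropy(p[: k + 1]) + entropy(p[k + 1 :])
    return crits


def exhaustive_otsu(counts: np.ndarray, edges: np.ndarray) -> float:
    """Exhaustive between-class-variance search over all bin splits."""
    return float(edges[int(np.argmax(otsu_criteria(counts, edges))) + 1])


def exhaustive_kapur(counts: np.ndarray, edges: np.ndarray) -> float:
    """Exhaustive maximum-entropy (Kapur) search over all bin splits."""
    return float(edges[int(np.argmax(kapur_criteria(counts, edges))) + 1])


def agrees_with_exhaustive(threshold: float, counts: np.ndarray,
                           edges: np.ndarray, method: str) -> bool:
    """Whether a returned bin-edge threshold agrees with exhaustive search.

    Agreement means the returned edge attains the oracle optimum. Criteria at
    adjacent splits can coincide up to double-precision rounding (observed
    relative gaps ~1e-16 on random histograms), in which case either edge is
    a correct answer; a relative slack of 1e-9 separates such degenerate ties
    from genuinely suboptimal splits, whose gaps are many orders larger.
    """
    crits = otsu_criteria(counts, edges) if method == "otsu" else kapur_criteria(counts, edges)
    k = int(np.flatnonzero(np.isclose(edges[1:-1], threshold, rtol=0, atol=1e-12))[0])
    best = crits.max()
    return bool(crits[k] >= best - 1e-9 * abs(best))


def threshold_from_pixels(pixels: np.ndarray, method: str, n_bins: int = 256) -> float:
    """Oracle threshold straight from a pixel set (256 equal-width bins over
    the observed range, bin-edge candidates, smallest-t tie-break)."""
    counts, edges = np.histogram(pixels, bins=n_bins, range=(pixels.min(), pixels.max()))
    fn = exhaustive_otsu if method == "otsu" else exhaustive_kapur
    return fn(counts, edges)


# --- morphology / labeling -------------------------------------------------

def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """8-connected components by explicit BFS; returns labels and pixel counts."""
    ny, nx = mask.shape
    labels = np.zeros((ny, nx), dtype=int)
    sizes = []
    next_label = 0
    for sy in range(ny):
        for sx in range(nx):
            if mask[sy, sx] and labels[sy, sx] == 0:
                next_label += 1
                stack = [(sy, sx)]
                labels[sy, sx] = next_label
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and labels[yy, xx] == 0:
                                labels[yy, xx] = next_label
                                stack.append((yy, xx))
                sizes.append(size)
    return labels, sizes


def brute_dilate(mask: np.ndarray, radius_um: float, pixel_size_um: float) -> np.ndarray:
    """Dilation by direct min-distance to the foreground coordinate list."""
    fg = np.argwhere(mask)
    out = np.zeros_like(mask)
    if fg.size == 0:
        return out
    r2 = (radius_um / pixel_size_um) ** 2
    ny, nx = mask.shape
    for y in range(ny):
        for x in range(nx):
            d2 = ((fg[:, 0] - y) ** 2 + (fg[:, 1] - x) ** 2).min()
            out[y, x] = d2 <= r2 + 1e-9
    return out


def size_filtered(mask: np.ndarray, min_area_um2: float, pixel_size_um: float) -> np.ndarray:
    """Foreground restricted to 8-connected components >= the area cut-off."""
    labels, sizes = flood_fill_label(mask)
    keep = np.zeros_like(mask)
    for lab, size in enumerate(sizes, start=1):
        if size * pixel_size_um**2 >= min_area_um2:
            keep |= labels == lab
    return keep


# --- rank-sum exact enumeration -------------------------------------------

def exact_ranksum(a: list[float], b: list[float]) -> tuple[float, float]:
    """Exact two-sided permutation rank-sum test on small samples.

    Returns (W, p): W is the midrank sum of the first sample; p the exact
    probability, over all group assignments of the pooled values, of a rank
    sum at least as far from its expectation.
    """
    pooled = list(a) + list(b)
    n1 = len(a)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    w_obs = sum(ranks[:n1])
    mu = n1 * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            hits += 1
    return w_obs, hits / total


def hypergeom_tail(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, N) by direct summation."""
    p = 0.0
    for i in range(k, min(K, N) + 1):
        p += math.comb(K, i) * math.comb(M - K, N - i) / math.comb(M, N)
    return p
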