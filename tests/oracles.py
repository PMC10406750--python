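"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity from its definition with plain
loops (or exhaustive enumeration), deliberately sharing no code with the
library implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def groupby_max_ratings(rows):
    """Brute-force (reader, case) -> max rating over a list of tuples."""
    out = {}
    for reader, case, rating in rows:
        key = (reader, case)
        out[key] = max(out.get(key, 0), rating)
    return out


def flood_fill_component(binary: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """8-connected flood fill from a seed pixel."""
    h, w = binary.shape
    comp = np.zeros_like(binary, dtype=bool)
    stack = [seed]
    while stack:
        r, c = stack.pop()
        if not (0 <= r < h and 0 <= c < w) or comp[r, c] or not binary[r, c]:
            continue
        comp[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr or dc:
                    stack.append((r + dr, c + dc))
    return comp


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Largest 8-connected component by exhaustive flood fills."""
    best = None
    seen = np.zeros_like(binary, dtype=bool)
    for r in range(binary.shape[0]):
        for c in range(binary.shape[1]):
            if binary[r, c] and not seen[r, c]:
                comp = flood_fill_component(binary, (r, c))
                seen |= comp
                if best is None or comp.sum() > best.sum():
                    best = comp
    return best


def bbox_by_scan(mask: np.ndarray):
    """Tight bounding box of true pixels by exhaustive coordinate scan."""
    coords = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    rs = [r for r, _ in coords]
    cs = [c for _, c in coords]
    return min(rs), max(rs) + 1, min(cs), max(cs) + 1


def lattice_retained_by_counting(mask: np.ndarray, block_size: int, coverage_min: float):
    """Retained lattice origins by per-tile pixel counting with loops."""
    h, w = mask.shape
    out = []
    for r in range(0, h - block_size + 1, block_size):
        for c in range(0, w - block_size + 1, block_size):
            count = 0
            for i in range(r, r + block_size):
                for j in range(c, c + block_size):
                    if mask[i, j]:
                        count += 1
            if count / block_size**2 >= coverage_min:
                out.append((r, c))
    return out


def exhaustive_largest_square(mask: np.ndarray):
    """Largest all-true square by enumerating every square, largest first.

    Returns (row, col, side), ties broken by smallest row, then column.
    """
    h, w = mask.shape
    for side in range(min(h, w), 0, -1):
        for r in range(h - side + 1):
            for c in range(w - side + 1):
                if mask[r : r + side, c : c + side].all():
                    return r, c, side
    return None


def quantize_minmax(region: np.ndarray, n_levels: int) -> np.ndarray:
    region = np.asarray(region, dtype=float)
    lo, hi = region.min(), region.max()
    if hi == lo:
        return np.zeros(region.shape, dtype=int)
    q = np.floor((region - lo) / (hi - lo) * n_levels).astype(int)
    q[q == n_levels] = n_levels - 1
    return q


def glcm_by_pair_enumeration(region, distance, n_levels, offsets, symmetric=True):
    """Co-occurrence matrix by per-pixel pair loops; direction-averaged."""
    q = quantize_minmax(region, n_levels)
    h, w = q.shape
    mats = []
    for dr, dc in offsets:
        m = np.zeros((n_levels, n_levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    m[q[r, c], q[r2, c2]] += 1
                    if symmetric:
                        m[q[r2, c2], q[r, c]] += 1
        mats.append(m / m.sum())
    return np.mean(mats, axis=0)


def haralick_by_direct_summation(p: np.ndarray) -> dict:
    """The 15 GLCM statistics from their definitions with explicit loops."""
    n = p.shape[0]
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))

    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if px[i] * py[j] > 0
    )
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))

    if sd_x * sd_y > 0:
        corr = sum(
            (i - mu_x) * (j - mu_y) * p[i][j] for i in range(n) for j in range(n)
        ) / (sd_x * sd_y)
    else:
        corr = 0.0

    sum_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    diff_avg = sum(k * p_diff[k] for k in range(n))
    return {
        "Correlation": corr,
        "Difference_entropy": ent(p_diff),
        "Dissimilarity": sum(abs(i - j) * p[i][j] for i in range(n) for j in range(n)),
        "Difference_variance": sum((k - diff_avg) ** 2 * p_diff[k] for k in range(n)),
        "Energy": sum(p[i][j] ** 2 for i in range(n) for j in range(n)),
        "Entropy": hxy,
        "Homogeneity": sum(p[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n)),
        "Information_measure_of_correlation1": imc1,
        "Information_measure_of_correlation2": imc2,
        "Maximum_probability": max(p[i][j] for i in range(n) for j in range(n)),
        "Sum_entropy": ent(p_sum),
        "Sum_variance": sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * n - 1)),
        "Cluster_prominence": sum(
            (i + j - mu_x - mu_y) ** 4 * p[i][j] for i in range(n) for j in range(n)
        ),
        "Cluster_shade": sum(
            (i + j - mu_x - mu_y) ** 3 * p[i][j] for i in range(n) for j in range(n)
        ),
        "Sum_of_squares_variance": sum(
            (i - mu_x) ** 2 * p[i][j] for i in range(n) for j in range(n)
        ),
    }


def ngtdm_coarseness_by_loops(region, window, n_levels, eps=1e-9):
    """Amadasun-King coarseness by explicit per-pixel loops."""
    q = quantize_minmax(region, n_levels)
    h, w = q.shape
    r = window // 2
    s = {}
    counts = {}
    n_valid = 0
    for i in range(r, h - r):
        for j in range(r, w - r):
            total = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if di or dj:
                        total += q[i + di, j + dj]
            a_bar = total / (window * window - 1)
            level = int(q[i, j])
            s[level] = s.get(level, 0.0) + abs(level - a_bar)
            counts[level] = counts.get(level, 0) + 1
            n_valid += 1
    weighted = sum((counts[lv] / n_valid) * s[lv] for lv in s)
    return 1.0 / (eps + weighted)


def auc_by_pair_counting(scores, labels01):
    """AUC by exhaustive positive-negative pair comparison, ties at 0.5."""
    pos = [s for s, y in zip(scores, labels01) if y == 1]
    neg = [s for s, y in zip(scores, labels01) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def kruskal_h_by_rank_formula(values, groups):
    """Kruskal-Wallis H with tie correction from the rank formula."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    n = len(values)
    labels = sorted(set(groups))
    h = 0.0
    for g in labels:
        rs = [ranks[i] for i in range(n) if groups[i] == g]
        h += len(rs) * (sum(rs) / len(rs) - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    # tie correction
    ties = 0.0
    seen = {}
    for v in values:
        seen[v] = seen.get(v, 0) + 1
    for t in seen.values():
        ties += t**3 - t
    denom = 1.0 - ties / (n**3 - n)
    return h / denom if denom > 0 else 0.0
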