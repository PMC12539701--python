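"""Independent reference implementations used only by the tests.

These are deliberately naive (scalar, loop-based, brute-force) renderings of
the mathematical definitions, written separately from the package code so
the two can disagree.
"""

import math

import numpy as np


def hsv_oracle(r, g, b):
    """Scalar HSV: H = atan2(sqrt(3)(G-B), 2R-G-B) in [0, 2pi), S = C/V, V = max."""
    v = max(r, g, b)
    c = v - min(r, g, b)
    if c == 0:
        return 0.0, 0.0, v
    h = math.atan2(math.sqrt(3.0) * (g - b), 2.0 * r - g - b)
    if h < 0:
        h += 2.0 * math.pi
    if h >= 2.0 * math.pi:
        h = 0.0
    return h, c / v, v


def xyz_oracle(r, g, b):
    x = 0.607 * r + 0.174 * g + 0.200 * b
    y = 0.299 * r + 0.587 * g + 0.114 * b
    z = 0.066 * g + 1.116 * b
    return x, y, z


def luv_oracle(x, y, z, u0=0.19793943, v0=0.46831096, y0=1.0, v_factor=6.0):
    yn = y / y0
    if yn > 0.008856:
        ell = 116.0 * yn ** (1.0 / 3.0) - 16.0
    else:
        ell = 903.3 * yn
    d = x + 15.0 * y + 3.0 * z
    if d <= 0:
        return ell, 0.0, 0.0
    u = 13.0 * ell * (4.0 * x / d - u0)
    v = 13.0 * ell * (v_factor * y / d - v0)
    return ell, u, v


def diag_oracle(p):
    """Explicit cross product ||U x P|| / ||U|| with U = [1,1,1]."""
    u = np.array([1.0, 1.0, 1.0])
    c = np.array(
        [
            u[1] * p[2] - u[2] * p[1],
            u[2] * p[0] - u[0] * p[2],
            u[0] * p[1] - u[1] * p[0],
        ]
    )
    return float(np.sqrt((c**2).sum()) / np.sqrt(3.0))


def otsu_bruteforce(hist):
    """Exhaustive between-class-variance maximizer over a 256-bin histogram.

    Returns the lowest threshold index t (classes: bins <= t vs > t) among
    maximizers, considering only splits leaving both classes nonempty.
    """
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(hist.size)
    best_t, best_v = None, -1.0
    for t in range(hist.size - 1):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12 * max(best_v, 1.0):
            best_t, best_v = t, v
    return best_t


def local_entropy_bruteforce(quantized, radius):
    """Truncated circular-patch entropy, directly from counted histograms."""
    H, W = quantized.shape
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            vals = [
                quantized[y + dy, x + dx]
                for dy, dx in offsets
                if 0 <= y + dy < H and 0 <= x + dx < W
            ]
            _, counts = np.unique(vals, return_counts=True)
            p = counts / counts.sum()
            out[y, x] = float(-(p * np.log2(p)).sum())
    return out


def lloyd_kmeans(points, init_centers, n_iter=200):
    """Plain full-batch Lloyd iteration run to convergence."""
    centers = np.array(init_centers, dtype=float)
    for _ in range(n_iter):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        new = centers.copy()
        for j in range(centers.shape[0]):
            sel = assign == j
            if sel.any():
                new[j] = points[sel].mean(axis=0)
        if np.allclose(new, centers, atol=1e-12):
            return new
        centers = new
    return centers


def nearest_centroid_scan(pixels, centroids):
    """Exhaustive nearest-centroid assignment, lowest index on ties."""
    out = np.empty(len(pixels), dtype=int)
    for i, p in enumerate(pixels):
        best_j, best_d = 0, np.inf
        for j, c in enumerate(centroids):
            d = float(((p - c) ** 2).sum())
            if d < best_d:
                best_j, best_d = j, d
        out[i] = best_j
    return out
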