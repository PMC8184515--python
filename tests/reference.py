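"""Independent reference implementations used as oracles by the test suite.

Everything here is written deliberately naively — explicit Python loops,
brute-force flood fill, closed-form statistics — and stays independent of
the code paths it checks in ``cascadefish``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special


# --------------------------------------------------------------------------
# ΔF/F: naive double-loop sliding lower-50% baseline
# --------------------------------------------------------------------------

def dff_reference(trace: np.ndarray, fps: float, window_s: float = 10.0) -> np.ndarray:
    """Explicit-loop ΔF/F: for each frame, sort the trailing window, average
    the ⌊k/2⌋ (min 1) smallest values, normalize."""
    trace = np.asarray(trace, dtype=float)
    W = int(round(window_s * fps))
    out = np.zeros(trace.size)
    for t in range(1, trace.size):
        win = sorted(trace[max(0, t - W) : t])
        m = max(1, len(win) // 2)
        base = sum(win[:m]) / m
        out[t] = (trace[t] - base) / base
    return out


# --------------------------------------------------------------------------
# Cascades: exhaustive flood fill + verbatim linking rule
# --------------------------------------------------------------------------

def _neighbors(r, c, connectivity):
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    return [(r + dr, c + dc) for dr, dc in offs]


def flood_fill_clusters(frame: np.ndarray, min_pixels: int = 3, connectivity: int = 4):
    """Connected components by explicit BFS; components < min_pixels dropped."""
    frame = np.asarray(frame, dtype=bool)
    seen = np.zeros_like(frame)
    clusters = []
    H, W = frame.shape
    for r0 in range(H):
        for c0 in range(W):
            if frame[r0, c0] and not seen[r0, c0]:
                comp = []
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for rr, cc in _neighbors(r, c, connectivity):
                        if 0 <= rr < H and 0 <= cc < W and frame[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                if len(comp) >= min_pixels:
                    clusters.append(set(comp))
    return clusters


def _contiguous(cluster: set, prev_pixels: set, connectivity: int) -> bool:
    for (r, c) in cluster:
        if (r, c) in prev_pixels:
            return True
        for rr, cc in _neighbors(r, c, connectivity):
            if (rr, cc) in prev_pixels:
                return True
    return False


def link_cascades_reference(
    binary_stack: np.ndarray, min_pixels: int = 3, connectivity: int = 4
):
    """Verbatim initiation/continuation/termination/merge rule, nested loops.

    Returns a list of dicts with keys start, end, size (cumulative
    (pixel, frame) activations), peak_extent and footprint.
    """
    ongoing = []   # each: {"frames": {frame: set of pixels}, "last": set}
    finished = []
    for t in range(binary_stack.shape[0]):
        clusters = flood_fill_clusters(binary_stack[t], min_pixels, connectivity)
        touches = [
            [
                i
                for i, casc in enumerate(ongoing)
                if _contiguous(cl, casc["last"], connectivity)
            ]
            for cl in clusters
        ]
        continued = {i for tc in touches for i in tc}
        finished.extend(c for i, c in enumerate(ongoing) if i not in continued)
        # merge ongoing cascades that share a continuing cluster (union-find)
        parent = {i: i for i in continued}

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for tc in touches:
            for i in tc[1:]:
                ri, rj = find(tc[0]), find(i)
                if ri != rj:
                    parent[rj] = ri
        new_ongoing = []
        root_to_new = {}
        for i in sorted(continued):
            root = find(i)
            if root not in root_to_new:
                root_to_new[root] = len(new_ongoing)
                new_ongoing.append({"frames": {}, "last": set()})
            merged = new_ongoing[root_to_new[root]]
            for f, pix in ongoing[i]["frames"].items():
                merged["frames"].setdefault(f, set()).update(pix)
        for cl, tc in zip(clusters, touches):
            if tc:
                target = new_ongoing[root_to_new[find(tc[0])]]
            else:
                target = {"frames": {}, "last": set()}
                new_ongoing.append(target)
            target["frames"].setdefault(t, set()).update(cl)
            target["last"].update(cl)
        ongoing = new_ongoing
    finished.extend(ongoing)
    out = []
    for casc in finished:
        frames = casc["frames"]
        size = sum(len(p) for p in frames.values())
        out.append(
            {
                "start": min(frames),
                "end": max(frames),
                "size": size,
                "peak_extent": max(len(p) for p in frames.values()),
                "footprint": {
                    (f, r, c) for f, pix in frames.items() for (r, c) in pix
                },
            }
        )
    out.sort(key=lambda d: (d["start"], sorted(d["footprint"])))
    return out


# --------------------------------------------------------------------------
# Coactivity / surrogate null: naive loops
# --------------------------------------------------------------------------

def coactivity_reference(events: np.ndarray, window: int = 10) -> np.ndarray:
    """counts(t) = # neurons with >= 1 event in frames [t-window+1, t]."""
    events = np.asarray(events, dtype=bool)
    n, T = events.shape
    counts = np.zeros(T, dtype=int)
    for t in range(T):
        lo = max(0, t - window + 1)
        for u in range(n):
            if events[u, lo : t + 1].any():
                counts[t] += 1
    return counts


def shuffle_null_reference(
    events: np.ndarray, n_shuffles: int, window: int, rng: np.random.Generator
) -> np.ndarray:
    """Pooled surrogate coactivity values from naive within-neuron shuffles."""
    events = np.asarray(events, dtype=bool)
    n, T = events.shape
    pooled = []
    for _ in range(n_shuffles):
        surr = np.zeros_like(events)
        for u in range(n):
            k = int(events[u].sum())
            if k:
                surr[u, rng.choice(T, size=k, replace=False)] = True
        pooled.append(coactivity_reference(surr, window))
    return np.concatenate(pooled)


# --------------------------------------------------------------------------
# Statistics: closed forms
# --------------------------------------------------------------------------

def _t_two_sided_p(t: float, df: float) -> float:
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


def pooled_t_reference(a, b):
    """Textbook pooled-variance two-sample t with two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, _t_two_sided_p(t, na + nb - 2)


def paired_t_reference(pre, post):
    """One-sample t on post - pre with two-sided p."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return t, _t_two_sided_p(t, n - 1)


def ks_reference(a, b):
    """Brute-force two-sample KS: sup ECDF difference over all sample points,
    with the asymptotic Kolmogorov p (series summed directly)."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    points = np.concatenate([a, b])
    d = 0.0
    for x in points:
        fa = np.sum(a <= x) / a.size
        fb = np.sum(b <= x) / b.size
        d = max(d, abs(fa - fb))
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    y = en * d
    p = 0.0
    for k in range(1, 101):
        p += 2 * (-1) ** (k - 1) * math.exp(-2 * (k * y) ** 2)
    return d, min(max(p, 0.0), 1.0)
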