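"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def assert_spot_lists_close(a, b, tol: float = 1e-6) -> None:
    """Equality of spot lists up to floating-point roundoff in the filter."""
    assert len(a) == len(b)
    for s, t in zip(a, b):
        assert s.spot_id == t.spot_id
        assert s.area_px == t.area_px
        assert s.n_positive_maxima == t.n_positive_maxima
        assert abs(s.centroid_x - t.centroid_x) < tol
        assert abs(s.centroid_y - t.centroid_y) < tol
        assert abs(s.integrated_signal - t.integrated_signal) < tol * max(1.0, abs(t.integrated_signal))
        assert abs(s.peak_value - t.peak_value) < tol * max(1.0, abs(t.peak_value))


def brute_force_extrema(arr: np.ndarray):
    """Literal 8-neighbour scan: the oracle for find_local_extrema.

    Checks every interior pixel against its 8 neighbours with plain loops,
    independently of the vectorized implementation.
    """
    h, w = arr.shape
    maxima, minima = [], []
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            c = arr[y, x]
            neigh = [
                arr[y + dy, x + dx]
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if not (dy == 0 and dx == 0)
            ]
            if all(c > v for v in neigh):
                maxima.append((x, y, c))
            if all(c < v for v in neigh):
                minima.append((x, y, c))
    return maxima, minima


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Connected components by explicit flood fill: oracle for label_spot_areas."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            stack = [(y0, x0)]
            seen[y0, x0] = True
            comp = []
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy, dx in steps:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            comps.append(frozenset(comp))
    return comps


def closed_form_ols(x: np.ndarray, y: np.ndarray):
    """Normal-equation least squares: oracle for fit_standard_curve."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    syy = (y * y).sum()
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return slope, intercept, r


def max_cardinality_matching(det: np.ndarray, tru: np.ndarray, radius: float) -> int:
    """Maximum one-to-one matching within a radius, via networkx: matching oracle."""
    import networkx as nx

    g = nx.Graph()
    dn = [("d", i) for i in range(len(det))]
    tn = [("t", j) for j in range(len(tru))]
    g.add_nodes_from(dn)
    g.add_nodes_from(tn)
    for i in range(len(det)):
        for j in range(len(tru)):
            if np.hypot(*(det[i] - tru[j])) <= radius:
                g.add_edge(("d", i), ("t", j))
    return len(nx.max_weight_matching(g, maxcardinality=True))
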