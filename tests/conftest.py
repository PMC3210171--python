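"""Shared fixtures and independent oracles.

The oracles deliberately use a different computational route from the
implementation (pure-Python loops, projection geometry, staged grid search)
so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from actc.synthetic import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A small but fully featured cartridge sample: 4 tiles, all object
    regimes, cartridge border on every edge."""
    return SimConfig(
        n_tiles=4,
        tile_shape=(128, 128),
        rng_seed=1,
        object_counts={"ctc": 3.0, "leukocyte": 6.0, "tmp": 4.0, "debris": 3.0},
    )


# ---------------------------------------------------------------------------
# oracle: triangle threshold by explicit per-bin projection geometry


def triangle_oracle(hist) -> int:
    """Exhaustive triangle threshold: for every bin between the histogram
    peak and the long-tail end, compute the perpendicular distance to the
    peak-tail chord by vector projection/rejection; return the argmax,
    lowest intensity on ties."""
    h = [float(v) for v in hist]
    nz = [i for i, v in enumerate(h) if v > 0]
    assert nz, "oracle needs a nonzero bin"
    peak = h.index(max(h))
    first, last = nz[0], nz[-1]
    if first == last:
        return first
    tail = last if (last - peak) >= (peak - first) else first
    px, py = float(peak), h[peak]
    tx, ty = float(tail), h[tail]
    length = math.hypot(tx - px, ty - py)
    vx, vy = (tx - px) / length, (ty - py) / length
    best_d, best_i = -1.0, None
    for i in range(min(peak, tail), max(peak, tail) + 1):
        wx, wy = i - px, h[i] - py
        proj = wx * vx + wy * vy
        d = math.hypot(wx - proj * vx, wy - proj * vy)
        if d > best_d + 1e-9:
            best_d, best_i = d, i
    return best_i


# ---------------------------------------------------------------------------
# oracle: Cox partial likelihood maximized by staged grid search (no ties)


def cox_loglik(beta: float, times, events, group) -> float:
    """Written-out Cox partial log-likelihood for distinct event times."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    ll = 0.0
    for k, i in enumerate(order):
        if events[i]:
            denom = sum(math.exp(beta * group[j]) for j in order[k:])
            ll += beta * group[i] - math.log(denom)
    return ll


def cox_grid_mle(times, events, group, lo: float = -6.0, hi: float = 6.0) -> float:
    """Brute-force maximization of :func:`cox_loglik` over a staged fine
    beta grid; returns the hazard ratio exp(beta_hat)."""
    for _ in range(4):
        grid = [lo + (hi - lo) * k / 1000 for k in range(1001)]
        vals = [cox_loglik(b, times, events, group) for b in grid]
        k = vals.index(max(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 1000)]
    return math.exp((lo + hi) / 2.0)


# ---------------------------------------------------------------------------
# oracle: rasterized disk pixel count


def disk_pixel_count(radius: float) -> int:
    """Number of integer lattice points within ``radius`` of the origin."""
    n = int(math.ceil(radius))
    return sum(
        1
        for y in range(-n, n + 1)
        for x in range(-n, n + 1)
        if y * y + x * x <= radius * radius
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
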