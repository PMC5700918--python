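"""Numba kernels for the lattice model's inner loops.

Individuals are updated sequentially in a shuffled order so that movement
collisions (occupied larval cells, full adult cells) are resolved one at a
time; all randomness comes from numba's per-thread RNG, seeded explicitly
through :func:`seed_kernel_rng` before every exposed step.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernel_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _draw_neighbour(r, c, R, H, W):
    """Uniform cell in the clipped Chebyshev ball of radius R, excluding
    the origin; returns the origin itself when the ball is empty (R=0)."""
    r0 = max(0, r - R)
    r1 = min(H - 1, r + R)
    c0 = max(0, c - R)
    c1 = min(W - 1, c + R)
    ncols = c1 - c0 + 1
    n = (r1 - r0 + 1) * ncols - 1
    if n <= 0:
        return r, c
    k = np.random.randint(0, n)
    origin = (r - r0) * ncols + (c - c0)
    if k >= origin:
        k += 1
    return r0 + k // ncols, c0 + k % ncols


@njit(cache=True)
def larval_step(larvae, crop, r_bt, r_nonbt):
    """In-place larval dispersal: each larva (shuffled order) draws one
    candidate within its crop-dependent radius and moves iff empty."""
    H, W = larvae.shape
    n = 0
    for i in range(H):
        for j in range(W):
            if larvae[i, j] == 1:
                n += 1
    rows = np.empty(n, dtype=np.int64)
    cols = np.empty(n, dtype=np.int64)
    k = 0
    for i in range(H):
        for j in range(W):
            if larvae[i, j] == 1:
                rows[k] = i
                cols[k] = j
                k += 1
    # Fisher-Yates shuffle of the update order
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        rows[i], rows[j] = rows[j], rows[i]
        cols[i], cols[j] = cols[j], cols[i]
    for k in range(n):
        r, c = rows[k], cols[k]
        R = r_bt if crop[r, c] == 1 else r_nonbt
        if R == 0:
            continue
        rr, cc = _draw_neighbour(r, c, R, H, W)
        if larvae[rr, cc] == 0:
            larvae[r, c] = 0
            larvae[rr, cc] = 1


@njit(cache=True)
def adult_step(adults, radius, K):
    """In-place adult dispersal: each female (shuffled order) draws one
    candidate within ``radius`` and moves iff below carrying capacity."""
    H, W = adults.shape
    total = 0
    for i in range(H):
        for j in range(W):
            total += adults[i, j]
    if total == 0:
        return
    rows = np.empty(total, dtype=np.int64)
    cols = np.empty(total, dtype=np.int64)
    k = 0
    for i in range(H):
        for j in range(W):
            for _ in range(adults[i, j]):
                rows[k] = i
                cols[k] = j
                k += 1
    for i in range(total - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        rows[i], rows[j] = rows[j], rows[i]
        cols[i], cols[j] = cols[j], cols[i]
    for k in range(total):
        r, c = rows[k], cols[k]
        if radius == 0:
            continue
        rr, cc = _draw_neighbour(r, c, radius, H, W)
        if (rr != r or cc != c) and adults[rr, cc] < K:
            adults[r, c] -= 1
            adults[rr, cc] += 1


@njit(cache=True)
def transition(larvae, adults, m_imm, m_meta, m_adult, p_ovi, K):
    """In-place demographic events, in fixed order: immature mortality,
    metamorphosis (larva removed, one female added to the same cell when
    below capacity), adult mortality, oviposition (each female lays at most
    one egg into her own cell's larval slot when empty)."""
    H, W = larvae.shape
    for i in range(H):
        for j in range(W):
            if larvae[i, j] == 1:
                if np.random.random() < m_imm:
                    larvae[i, j] = 0
                elif np.random.random() < m_meta:
                    larvae[i, j] = 0
                    if adults[i, j] < K:
                        adults[i, j] += 1
    for i in range(H):
        for j in range(W):
            a = adults[i, j]
            if a > 0:
                dead = 0
                for _ in range(a):
                    if np.random.random() < m_adult:
                        dead += 1
                adults[i, j] = a - dead
    for i in range(H):
        for j in range(W):
            a = adults[i, j]
            if a > 0 and larvae[i, j] == 0:
                for _ in range(a):
                    if np.random.random() < p_ovi:
                        larvae[i, j] = 1
                        break


@njit(cache=True)
def run_steps(larvae, adults, crop, r_bt, r_nonbt, adult_radius, K,
              m_imm, m_meta, m_adult, p_ovi, steps):
    """Full replicate loop (transition -> larval -> adult dispersal per
    step); returns the number of steps actually executed (stops early on
    total extinction)."""
    done = 0
    for _ in range(steps):
        if larvae.sum() == 0 and adults.sum() == 0:
            break
        transition(larvae, adults, m_imm, m_meta, m_adult, p_ovi, K)
        larval_step(larvae, crop, r_bt, r_nonbt)
        adult_step(adults, adult_radius, K)
        done += 1
    return done
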