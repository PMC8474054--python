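"""Compiled kinetic Monte Carlo kernel for production-length trajectories.

Same algorithm as :mod:`polcond.reference` — rate catalog, tower sampling in
the canonical transition order, Arrhenius rates, local [x±4, y±4] catalog
refresh — but operating on flat numpy arrays under numba. Both engines
consume an identical stream of pre-drawn uniforms, so given the same seed
they produce bit-identical trajectories (verified in the test suite).

Catalog layout: per-site particle rates ``prate[y, x, 8]`` in the fixed
Moore-neighbor order, and per-monomer polymer rates ``mrate[c, i, 4]`` with
slots [end-flip A, end-flip B, kink jump, crankshaft]. Per-entity subtotals
are recomputed exactly whenever an entity is touched; the running total rate
is re-summed exactly every 1e5 steps to bound floating drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import KineticParams
from .lattice import (
    MOORE_OFFSETS,
    AffinityMatrix,
    LatticeState,
    PolymerChain,
    Species,
    energy_offsets,
)

__all__ = ["KernelState", "run_kernel_chunk"]

RESUM_INTERVAL = 100_000

_S5P = int(Species.S5P)
_EMPTY = int(Species.EMPTY)

_MOFF = np.array(MOORE_OFFSETS, dtype=np.int64)


@njit(cache=True)
def _de_single(grid, eoff, w, sy, sx, ty, tx, sp):
    H, W = grid.shape
    e1 = 0.0
    for k in range(eoff.shape[0]):
        ny = sy + eoff[k, 0]
        nx = sx + eoff[k, 1]
        if 0 <= ny < H and 0 <= nx < W:
            e1 += w[sp, grid[ny, nx]]
    e2 = 0.0
    for k in range(eoff.shape[0]):
        ny = ty + eoff[k, 0]
        nx = tx + eoff[k, 1]
        if 0 <= ny < H and 0 <= nx < W and not (ny == sy and nx == sx):
            e2 += w[sp, grid[ny, nx]]
    return e2 - e1


@njit(cache=True)
def _adjacent(eoff, ay, ax, by, bx):
    for k in range(eoff.shape[0]):
        if ay + eoff[k, 0] == by and ax + eoff[k, 1] == bx:
            return True
    return False


@njit(cache=True)
def _de_double(grid, eoff, w, s1y, s1x, t1y, t1x, sp1,
               s2y, s2x, t2y, t2x, sp2):
    H, W = grid.shape
    e1 = 0.0
    e2 = 0.0
    for which in range(2):
        if which == 0:
            oy, ox, nyt, nxt, sp = s1y, s1x, t1y, t1x, sp1
        else:
            oy, ox, nyt, nxt, sp = s2y, s2x, t2y, t2x, sp2
        for k in range(eoff.shape[0]):
            ny = oy + eoff[k, 0]
            nx = ox + eoff[k, 1]
            if 0 <= ny < H and 0 <= nx < W:
                if (ny == s1y and nx == s1x) or (ny == s2y and nx == s2x):
                    continue
                e1 += w[sp, grid[ny, nx]]
            ny = nyt + eoff[k, 0]
            nx = nxt + eoff[k, 1]
            if 0 <= ny < H and 0 <= nx < W:
                if (ny == s1y and nx == s1x) or (ny == s2y and nx == s2x):
                    continue
                e2 += w[sp, grid[ny, nx]]
    if _adjacent(eoff, s1y, s1x, s2y, s2x):
        e1 += w[sp1, sp2]
    if _adjacent(eoff, t1y, t1x, t2y, t2x):
        e2 += w[sp1, sp2]
    return e2 - e1


@njit(cache=True)
def _recompute_site(grid, eoff, w, moff, kp, prate, site_tot, y, x):
    """Refresh the 8 hop rates of site (y, x); returns subtotal change."""
    H, W = grid.shape
    old = site_tot[y, x]
    tot = 0.0
    if grid[y, x] == 1:  # S5P
        for d in range(8):
            ny = y + moff[d, 0]
            nx = x + moff[d, 1]
            if 0 <= ny < H and 0 <= nx < W and grid[ny, nx] == 0:
                de = _de_single(grid, eoff, w, y, x, ny, nx, 1)
                r = kp * np.exp(-de)
            else:
                r = 0.0
            prate[y, x, d] = r
            tot += r
    else:
        for d in range(8):
            prate[y, x, d] = 0.0
    site_tot[y, x] = tot
    return tot - old


@njit(cache=True)
def _recompute_monomer(grid, eoff, w, kkink, kcrank, cpos, clen, cspec,
                       mrate, mty, mtx, m2ty, m2tx, mono_tot, c, i):
    """Refresh the 4 move slots of monomer (c, i); returns subtotal change."""
    H, W = grid.shape
    old = mono_tot[c, i]
    for s in range(4):
        mrate[c, i, s] = 0.0
    L = clen[c]
    sp = cspec[c, i]
    py = cpos[c, i, 0]
    px = cpos[c, i, 1]
    tot = 0.0

    # end flip (slots 0, 1)
    if L >= 2 and (i == 0 or i == L - 1):
        j = 1 if i == 0 else L - 2
        vy = cpos[c, j, 0]
        vx = cpos[c, j, 1]
        dy = py - vy
        if dy != 0:
            c0y, c0x, c1y, c1x = vy, vx - 1, vy, vx + 1
        else:
            c0y, c0x, c1y, c1x = vy - 1, vx, vy + 1, vx
        for s in range(2):
            ty = c0y if s == 0 else c1y
            tx = c0x if s == 0 else c1x
            if 0 <= ty < H and 0 <= tx < W and grid[ty, tx] == 0:
                de = _de_single(grid, eoff, w, py, px, ty, tx, sp)
                r = kkink * np.exp(-de)
                mrate[c, i, s] = r
                mty[c, i, s] = ty
                mtx[c, i, s] = tx
                tot += r

    # kink jump (slot 2)
    if 0 < i < L - 1:
        ay = cpos[c, i - 1, 0]
        ax = cpos[c, i - 1, 1]
        by = cpos[c, i + 1, 0]
        bx = cpos[c, i + 1, 1]
        if ay != by and ax != bx:
            ty = ay + by - py
            tx = ax + bx - px
            if 0 <= ty < H and 0 <= tx < W and grid[ty, tx] == 0:
                de = _de_single(grid, eoff, w, py, px, ty, tx, sp)
                r = kkink * np.exp(-de)
                mrate[c, i, 2] = r
                mty[c, i, 2] = ty
                mtx[c, i, 2] = tx
                tot += r

    # crankshaft for the pair (i, i+1) (slot 3)
    if 1 <= i <= L - 3:
        e1y = cpos[c, i - 1, 0]
        e1x = cpos[c, i - 1, 1]
        e2y = cpos[c, i + 2, 0]
        e2x = cpos[c, i + 2, 1]
        q2y = cpos[c, i + 1, 0]
        q2x = cpos[c, i + 1, 1]
        by = e2y - e1y
        bx = e2x - e1x
        if abs(by) + abs(bx) == 1:
            n1y = py - e1y
            n1x = px - e1x
            if (abs(n1y) + abs(n1x) == 1
                    and q2y - e2y == n1y and q2x - e2x == n1x):
                t1y = e1y - n1y
                t1x = e1x - n1x
                t2y = e2y - n1y
                t2x = e2x - n1x
                if (0 <= t1y < H and 0 <= t1x < W and grid[t1y, t1x] == 0
                        and 0 <= t2y < H and 0 <= t2x < W
                        and grid[t2y, t2x] == 0):
                    sp2 = cspec[c, i + 1]
                    de = _de_double(grid, eoff, w, py, px, t1y, t1x, sp,
                                    q2y, q2x, t2y, t2x, sp2)
                    r = kcrank * np.exp(-de)
                    mrate[c, i, 3] = r
                    mty[c, i, 3] = t1y
                    mtx[c, i, 3] = t1x
                    m2ty[c, i] = t2y
                    m2tx[c, i] = t2x
                    tot += r
    mono_tot[c, i] = tot
    return tot - old


@njit(cache=True)
def _rebuild_all(grid, eoff, w, moff, kp, kkink, kcrank,
                 cpos, clen, cspec, prate, site_tot,
                 mrate, mty, mtx, m2ty, m2tx, mono_tot):
    H, W = grid.shape
    total = 0.0
    for y in range(H):
        for x in range(W):
            _recompute_site(grid, eoff, w, moff, kp, prate, site_tot, y, x)
            total += site_tot[y, x]
    for c in range(clen.shape[0]):
        for i in range(clen[c]):
            _recompute_monomer(grid, eoff, w, kkink, kcrank, cpos, clen,
                               cspec, mrate, mty, mtx, m2ty, m2tx,
                               mono_tot, c, i)
            total += mono_tot[c, i]
    return total


@njit(cache=True)
def _exact_total(site_tot, mono_tot, clen):
    total = 0.0
    H, W = site_tot.shape
    for y in range(H):
        for x in range(W):
            total += site_tot[y, x]
    for c in range(clen.shape[0]):
        for i in range(clen[c]):
            total += mono_tot[c, i]
    return total


@njit(cache=True)
def _run_chunk(n_steps, u, grid, chain_id, mono_ix, cpos, clen, cspec,
               eoff, w, moff, kp, kkink, kcrank,
               prate, site_tot, mrate, mty, mtx, m2ty, m2tx, mono_tot,
               pstamp, mstamp, scalars, changed, dwell, dwell_on,
               resum_interval, radius):
    """Advance n_steps iterations. ``scalars`` = [k_total, t, step, stamp, mask].

    Returns 0 on success, 1 if the system jammed (k_total == 0).
    """
    H, W = grid.shape
    k_total = scalars[0]
    t_now = scalars[1]
    step = int(scalars[2])
    stamp = int(scalars[3])
    mask = int(scalars[4])

    for s in range(n_steps):
        if step % resum_interval == 0:
            k_total = _exact_total(site_tot, mono_tot, clen)
        if k_total <= 0.0:
            scalars[0] = k_total
            scalars[1] = t_now
            scalars[2] = float(step)
            scalars[3] = float(stamp)
            scalars[4] = float(mask)
            return 1

        r1 = 1.0 - u[s, 0]
        kstar = r1 * k_total

        # --- tower sampling in canonical order: sites, then monomers ---
        sel_kind = -1   # 0 particle, 1 polymer
        sel_a = 0
        sel_b = 0
        sel_d = 0
        cum = 0.0
        for y in range(H):
            if sel_kind >= 0:
                break
            for x in range(W):
                st = site_tot[y, x]
                if st > 0.0 and cum + st >= kstar:
                    for d in range(8):
                        r = prate[y, x, d]
                        cum += r
                        if r > 0.0 and cum >= kstar:
                            sel_kind = 0
                            sel_a = y
                            sel_b = x
                            sel_d = d
                            break
                    if sel_kind < 0:
                        # rounding inside the site: take its last move
                        for d in range(7, -1, -1):
                            if prate[y, x, d] > 0.0:
                                sel_kind = 0
                                sel_a = y
                                sel_b = x
                                sel_d = d
                                break
                    break
                cum += st
        if sel_kind < 0:
            for c in range(clen.shape[0]):
                if sel_kind >= 0:
                    break
                for i in range(clen[c]):
                    mt = mono_tot[c, i]
                    if mt > 0.0 and cum + mt >= kstar:
                        for sl in range(4):
                            r = mrate[c, i, sl]
                            cum += r
                            if r > 0.0 and cum >= kstar:
                                sel_kind = 1
                                sel_a = c
                                sel_b = i
                                sel_d = sl
                                break
                        if sel_kind < 0:
                            for sl in range(3, -1, -1):
                                if mrate[c, i, sl] > 0.0:
                                    sel_kind = 1
                                    sel_a = c
                                    sel_b = i
                                    sel_d = sl
                                    break
                        break
                    cum += mt
        if sel_kind < 0:
            # terminal rounding overrun: take the last positive-rate move
            for y in range(H - 1, -1, -1):
                if sel_kind >= 0:
                    break
                for x in range(W - 1, -1, -1):
                    if site_tot[y, x] > 0.0:
                        for d in range(7, -1, -1):
                            if prate[y, x, d] > 0.0:
                                sel_kind = 0
                                sel_a = y
                                sel_b = x
                                sel_d = d
                                break
                        break
            for c in range(clen.shape[0] - 1, -1, -1):
                if sel_kind == 1:
                    break
                for i in range(clen[c] - 1, -1, -1):
                    if mono_tot[c, i] > 0.0:
                        for sl in range(3, -1, -1):
                            if mrate[c, i, sl] > 0.0:
                                sel_kind = 1
                                sel_a = c
                                sel_b = i
                                sel_d = sl
                                break
                        break
        if sel_kind < 0:
            scalars[0] = 0.0
            scalars[1] = t_now
            scalars[2] = float(step)
            scalars[3] = float(stamp)
            scalars[4] = float(mask)
            return 1

        # --- waiting time; dwell of the *current* configuration ---
        r2 = 1.0 - u[s, 1]
        dt = -np.log(r2) / k_total
        if dwell_on == 1:
            dwell[mask] += dt
        t_now += dt

        # --- apply ---
        n_changed = 0
        if sel_kind == 0:
            sy = sel_a
            sx = sel_b
            ty = sy + moff[sel_d, 0]
            tx = sx + moff[sel_d, 1]
            grid[sy, sx] = 0
            grid[ty, tx] = 1
            if dwell_on == 1:
                mask = mask ^ (1 << (sy * W + sx)) ^ (1 << (ty * W + tx))
            changed[0, 0] = sy
            changed[0, 1] = sx
            changed[1, 0] = ty
            changed[1, 1] = tx
            n_changed = 2
        else:
            c = sel_a
            i = sel_b
            sl = sel_d
            sy = cpos[c, i, 0]
            sx = cpos[c, i, 1]
            ty = mty[c, i, sl]
            tx = mtx[c, i, sl]
            sp = cspec[c, i]
            grid[sy, sx] = 0
            chain_id[sy, sx] = -1
            mono_ix[sy, sx] = -1
            grid[ty, tx] = sp
            chain_id[ty, tx] = c
            mono_ix[ty, tx] = i
            cpos[c, i, 0] = ty
            cpos[c, i, 1] = tx
            changed[0, 0] = sy
            changed[0, 1] = sx
            changed[1, 0] = ty
            changed[1, 1] = tx
            n_changed = 2
            if sl == 3:  # crankshaft: second monomer i+1
                s2y = cpos[c, i + 1, 0]
                s2x = cpos[c, i + 1, 1]
                t2y_ = m2ty[c, i]
                t2x_ = m2tx[c, i]
                sp2 = cspec[c, i + 1]
                grid[s2y, s2x] = 0
                chain_id[s2y, s2x] = -1
                mono_ix[s2y, s2x] = -1
                grid[t2y_, t2x_] = sp2
                chain_id[t2y_, t2x_] = c
                mono_ix[t2y_, t2x_] = i + 1
                cpos[c, i + 1, 0] = t2y_
                cpos[c, i + 1, 1] = t2x_
                changed[2, 0] = s2y
                changed[2, 1] = s2x
                changed[3, 0] = t2y_
                changed[3, 1] = t2x_
                n_changed = 4

        # --- local catalog refresh around changed sites ---
        # Catalog entries depend on occupancy within Chebyshev distance 3
        # (move targets reach distance 2, plus a one-site energy shell), so
        # refreshing this window reproduces a full rebuild exactly.
        stamp += 1
        delta = 0.0
        for q in range(n_changed):
            cy = changed[q, 0]
            cx = changed[q, 1]
            y0 = cy - radius if cy - radius > 0 else 0
            y1 = cy + radius + 1 if cy + radius + 1 < H else H
            x0 = cx - radius if cx - radius > 0 else 0
            x1 = cx + radius + 1 if cx + radius + 1 < W else W
            for yy in range(y0, y1):
                for xx in range(x0, x1):
                    if pstamp[yy, xx] != stamp:
                        pstamp[yy, xx] = stamp
                        delta += _recompute_site(grid, eoff, w, moff, kp,
                                                 prate, site_tot, yy, xx)
                    cc = chain_id[yy, xx]
                    if cc >= 0:
                        mi = mono_ix[yy, xx]
                        j0 = mi - 2 if mi - 2 > 0 else 0
                        j1 = mi + 3 if mi + 3 < clen[cc] else clen[cc]
                        for j in range(j0, j1):
                            if mstamp[cc, j] != stamp:
                                mstamp[cc, j] = stamp
                                delta += _recompute_monomer(
                                    grid, eoff, w, kkink, kcrank, cpos, clen,
                                    cspec, mrate, mty, mtx, m2ty, m2tx,
                                    mono_tot, cc, j)
        k_total += delta
        step += 1

    scalars[0] = k_total
    scalars[1] = t_now
    scalars[2] = float(step)
    scalars[3] = float(stamp)
    scalars[4] = float(mask)
    return 0


class KernelState:
    """Array view of a lattice state plus its live rate catalog."""

    def __init__(self, state: LatticeState, w: AffinityMatrix,
                 kinetics: KineticParams, neighborhood: str = "moore",
                 record_dwell: bool = False,
                 update_radius: int | None = None):
        H, W = state.height, state.width
        self.height, self.width = H, W
        self.grid = state.grid.astype(np.int64).copy()
        self.chain_id = state.chain_id.astype(np.int64).copy()
        self.mono_ix = state.mono_ix.astype(np.int64).copy()
        C = len(state.chains)
        Lmax = max([c.length for c in state.chains], default=1)
        self.cpos = np.zeros((C, Lmax, 2), dtype=np.int64)
        self.cspec = np.zeros((C, Lmax), dtype=np.int64)
        self.clen = np.zeros(C, dtype=np.int64)
        for c, chain in enumerate(state.chains):
            self.clen[c] = chain.length
            self.cpos[c, :chain.length] = chain.coords
            self.cspec[c, :chain.length] = chain.species
        self.eoff = np.array(energy_offsets(neighborhood), dtype=np.int64)
        self.moff = _MOFF
        self.w = np.asarray(w.matrix, dtype=np.float64)
        self.kp = float(kinetics.k_p)
        self.kkink = float(kinetics.k_kink)
        self.kcrank = float(kinetics.k_crank)

        self.prate = np.zeros((H, W, 8), dtype=np.float64)
        self.site_tot = np.zeros((H, W), dtype=np.float64)
        self.mrate = np.zeros((C, Lmax, 4), dtype=np.float64)
        self.mty = np.zeros((C, Lmax, 4), dtype=np.int64)
        self.mtx = np.zeros((C, Lmax, 4), dtype=np.int64)
        self.m2ty = np.zeros((C, Lmax), dtype=np.int64)
        self.m2tx = np.zeros((C, Lmax), dtype=np.int64)
        self.mono_tot = np.zeros((C, Lmax), dtype=np.float64)
        # particle hops only depend on occupancy within distance 2; chain
        # moves within 3 — refresh the tightest window that is provably
        # identical to a full rebuild
        if update_radius is None:
            update_radius = 3 if C > 0 else 2
        self.update_radius = int(update_radius)
        self.pstamp = np.zeros((H, W), dtype=np.int64)
        self.mstamp = np.zeros((C, Lmax), dtype=np.int64)
        self.changed = np.zeros((4, 2), dtype=np.int64)

        self.record_dwell = bool(record_dwell)
        if self.record_dwell:
            if H * W > 24:
                raise ValueError("dwell recording needs W*H <= 24 sites")
            if C > 0:
                raise ValueError("dwell recording supports particle-only systems")
            self.dwell = np.zeros(1 << (H * W), dtype=np.float64)
            mask = 0
            for (y, x) in state.particle_sites():
                mask |= 1 << (y * W + x)
        else:
            self.dwell = np.zeros(1, dtype=np.float64)
            mask = 0

        k_total = _rebuild_all(
            self.grid, self.eoff, self.w, self.moff, self.kp, self.kkink,
            self.kcrank, self.cpos, self.clen, self.cspec, self.prate,
            self.site_tot, self.mrate, self.mty, self.mtx, self.m2ty,
            self.m2tx, self.mono_tot)
        # scalars: [k_total, t, step, stamp, occupancy bitmask]
        self.scalars = np.array([k_total, 0.0, 0.0, 0.0, float(mask)],
                                dtype=np.float64)
        self.jammed = False

    @property
    def k_total(self) -> float:
        return float(self.scalars[0])

    @property
    def time(self) -> float:
        return float(self.scalars[1])

    @property
    def step(self) -> int:
        return int(self.scalars[2])

    def run(self, n_steps: int, draws: np.ndarray,
            resum_interval: int = RESUM_INTERVAL) -> bool:
        """Advance ``n_steps`` steps; returns True if the system jammed."""
        if self.jammed:
            return True
        status = _run_chunk(
            n_steps, np.asarray(draws, dtype=np.float64),
            self.grid, self.chain_id, self.mono_ix, self.cpos, self.clen,
            self.cspec, self.eoff, self.w, self.moff, self.kp, self.kkink,
            self.kcrank, self.prate, self.site_tot, self.mrate, self.mty,
            self.mtx, self.m2ty, self.m2tx, self.mono_tot, self.pstamp,
            self.mstamp, self.scalars, self.changed, self.dwell,
            1 if self.record_dwell else 0, resum_interval,
            self.update_radius)
        self.jammed = status == 1
        return self.jammed

    def snapshot(self) -> LatticeState:
        """Materialize the current configuration as a LatticeState."""
        out = LatticeState(self.width, self.height)
        out.grid = self.grid.copy()
        out.chain_id = self.chain_id.copy()
        out.mono_ix = self.mono_ix.copy()
        out.chains = [
            PolymerChain(self.cpos[c, :self.clen[c]].copy(),
                         self.cspec[c, :self.clen[c]].copy())
            for c in range(self.clen.shape[0])
        ]
        return out


def run_kernel_chunk(kernel: KernelState, n_steps: int,
                     rng: np.random.Generator) -> bool:
    """Draw the uniform stream for a chunk and advance the kernel."""
    draws = rng.random((n_steps, 2))
    return kernel.run(n_steps, draws)
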