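"""Flat-array growth engine with numba kernels.

The object model in :mod:`vasctree.vessel_tree` is convenient but too slow to
evaluate thousands of provisional trees per added terminal.  This module
mirrors a tree into structure-of-arrays form and evaluates candidate
insertions with jitted kernels: every candidate triggers a *full* tree
rescale (flows, betas, radii) so the returned cost difference is exact even
under mixed frozen/free terminal-flow policies, where an insertion perturbs
flow ratios away from the insertion path.

Rows are dense: a split reuses the parent's row for the proximal stub and
appends two rows (sibling, new terminal).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_PI = math.pi


# --------------------------------------------------------------------- kernels
@njit(cache=True)
def _postorder(left, right, root, n):
    s1 = np.empty(n, np.int64)
    out = np.empty(n, np.int64)
    t1 = 0
    t2 = n
    s1[t1] = root
    t1 += 1
    while t1 > 0:
        t1 -= 1
        v = s1[t1]
        t2 -= 1
        out[t2] = v
        if left[v] != -1:
            s1[t1] = left[v]
            t1 += 1
            s1[t1] = right[v]
            t1 += 1
    return out[t2:].copy()


@njit(cache=True, inline="always")
def _seg_len(xp, xd, i):
    dx = xd[i, 0] - xp[i, 0]
    dy = xd[i, 1] - xp[i, 1]
    dz = xd[i, 2] - xp[i, 2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _eval_core(post, left, right, xp, xd, mu, frozen, qfix, q_free,
               gamma, gamma_f, cv, cp_, cd, v_ref, l_ref, r_ref, r0,
               Q, rstar, beta, acc_a, acc_b, rad):
    """Bottom-up reduced resistance + cost aggregates, top-down radii.

    Returns the total tree cost.  ``post`` orders children before parents;
    aggregates: acc_a = sum l_j (prod beta)^(gamma_f - 1), acc_b = sum
    (prod beta), both relative to the subtree root radius.
    """
    e = gamma_f - 1.0
    g3 = gamma == 3.0
    e2 = e == 2.0
    inv_g = -1.0 / gamma
    d_term = 0.0
    for k in range(post.shape[0]):
        i = post[k]
        li = _seg_len(xp, xd, i)
        d_term += cd * (li / l_ref) * (li / l_ref)
        if left[i] == -1:
            Q[i] = qfix[i] if frozen[i] == 1 else q_free
            rstar[i] = 8.0 * mu[i] * li / _PI
            acc_a[i] = li
            acc_b[i] = 1.0
        else:
            l_, r_ = left[i], right[i]
            num = Q[r_] * rstar[r_]
            den = Q[l_] * rstar[l_]
            xi = math.sqrt(math.sqrt(num / den))  # r_r / r_l
            if g3:
                bl = (1.0 + xi * xi * xi) ** (-1.0 / 3.0)
            else:
                bl = (1.0 + xi ** gamma) ** inv_g
            br = xi * bl  # (1 + xi^-g)^(-1/g) == xi (1 + xi^g)^(-1/g)
            beta[l_] = bl
            beta[r_] = br
            Q[i] = Q[l_] + Q[r_]
            bl2 = bl * bl
            br2 = br * br
            rstar[i] = 8.0 * mu[i] * li / _PI + 1.0 / (
                bl2 * bl2 / rstar[l_] + br2 * br2 / rstar[r_]
            )
            if e2:
                acc_a[i] = li + bl2 * acc_a[l_] + br2 * acc_a[r_]
            else:
                acc_a[i] = li + bl ** e * acc_a[l_] + br ** e * acc_a[r_]
            acc_b[i] = 1.0 + bl * acc_b[l_] + br * acc_b[r_]
    root = post[post.shape[0] - 1]
    beta[root] = 1.0
    rad[root] = r0
    for k in range(post.shape[0] - 1, -1, -1):
        i = post[k]
        if left[i] != -1:
            rad[left[i]] = beta[left[i]] * rad[i]
            rad[right[i]] = beta[right[i]] * rad[i]
    cost = (cv * _PI * r0 ** e * acc_a[root] / v_ref ** (gamma_f / 3.0)
            + cp_ * r0 * acc_b[root] / r_ref + d_term)
    return cost


@njit(cache=True, inline="always")
def _seg_seg_dist(p0x, p0y, p0z, p1x, p1y, p1z,
                  q0x, q0y, q0z, q1x, q1y, q1z):
    """Minimum distance between segments p0-p1 and q0-q1 (clamped closest points)."""
    ux, uy, uz = p1x - p0x, p1y - p0y, p1z - p0z
    vx, vy, vz = q1x - q0x, q1y - q0y, q1z - q0z
    wx, wy, wz = p0x - q0x, p0y - q0y, p0z - q0z
    a = ux * ux + uy * uy + uz * uz
    b = ux * vx + uy * vy + uz * vz
    c = vx * vx + vy * vy + vz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    den = a * c - b * b
    if den > 1e-14 * a * c + 1e-300:
        s = (b * e - c * d) / den
    else:
        s = 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    if c > 1e-300:
        t = (b * s + e) / c
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    # refine s for clamped t
    if a > 1e-300:
        s = (b * t - d) / a
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    dx = wx + s * ux - t * vx
    dy = wy + s * uy - t * vy
    dz = wz + s * uz - t * vz
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _terminal_collision_free(n, skip_row, bif, x_new, xp, xd, rad, r_term):
    """True when the candidate terminal segment keeps a sum-of-radii gap to
    every vessel except the split parent (checked against current radii)."""
    for j in range(n):
        if j == skip_row:
            continue
        dmin = _seg_seg_dist(
            bif[0], bif[1], bif[2], x_new[0], x_new[1], x_new[2],
            xp[j, 0], xp[j, 1], xp[j, 2], xd[j, 0], xd[j, 1], xd[j, 2],
        )
        if dmin < r_term + rad[j]:
            return False
    return True


@njit(cache=True)
def _point_seg_dists(x, xp, xd, n, out):
    for i in range(n):
        ux = xd[i, 0] - xp[i, 0]
        uy = xd[i, 1] - xp[i, 1]
        uz = xd[i, 2] - xp[i, 2]
        wx = x[0] - xp[i, 0]
        wy = x[1] - xp[i, 1]
        wz = x[2] - xp[i, 2]
        a = ux * ux + uy * uy + uz * uz
        t = 0.0
        if a > 1e-300:
            t = (ux * wx + uy * wy + uz * wz) / a
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
        dx = wx - t * ux
        dy = wy - t * uy
        dz = wz - t * uz
        out[i] = math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _eval_candidates(n, post, pos_in_post, parent, left, right, xp, xd,
                     mu, frozen, qfix, q_free_new, gamma, gamma_f,
                     cv, cp_, cd, v_ref, l_ref, r_ref, r0,
                     cand_parent, cand_bif, x_new, mu_new,
                     Q, rstar, beta, acc_a, acc_b, rad, post2,
                     out_cost, out_rstub, out_rsib, out_rterm):
    """Evaluate every candidate insertion with a full provisional rescale.

    Mutates the topology arrays in place per candidate and restores them;
    rows ``n`` and ``n+1`` are scratch (sibling, terminal).
    """
    sib = n
    term = n + 1
    xd[term, 0] = x_new[0]
    xd[term, 1] = x_new[1]
    xd[term, 2] = x_new[2]
    left[term] = -1
    right[term] = -1
    frozen[term] = 0
    qfix[term] = 0.0
    mu[term] = mu_new
    for k in range(cand_parent.shape[0]):
        p = cand_parent[k]
        # save parent row
        sxd0, sxd1, sxd2 = xd[p, 0], xd[p, 1], xd[p, 2]
        sl, sr = left[p], right[p]
        # sibling inherits the parent's distal part
        xp[sib, 0] = cand_bif[k, 0]
        xp[sib, 1] = cand_bif[k, 1]
        xp[sib, 2] = cand_bif[k, 2]
        xd[sib, 0], xd[sib, 1], xd[sib, 2] = sxd0, sxd1, sxd2
        left[sib] = sl
        right[sib] = sr
        frozen[sib] = frozen[p]
        qfix[sib] = qfix[p]
        mu[sib] = mu[p]
        xp[term, 0] = cand_bif[k, 0]
        xp[term, 1] = cand_bif[k, 1]
        xp[term, 2] = cand_bif[k, 2]
        # stub keeps row p
        xd[p, 0] = cand_bif[k, 0]
        xd[p, 1] = cand_bif[k, 1]
        xd[p, 2] = cand_bif[k, 2]
        left[p] = sib
        right[p] = term
        # provisional post-order: children of p (already before p), sib, term, p
        pos = pos_in_post[p]
        for j in range(pos):
            post2[j] = post[j]
        post2[pos] = sib
        post2[pos + 1] = term
        post2[pos + 2] = p
        for j in range(pos + 1, n):
            post2[j + 2] = post[j]
        cost = _eval_core(post2[: n + 2], left, right, xp, xd, mu, frozen,
                          qfix, q_free_new, gamma, gamma_f, cv, cp_, cd,
                          v_ref, l_ref, r_ref, r0, Q, rstar, beta,
                          acc_a, acc_b, rad)
        out_cost[k] = cost
        out_rstub[k] = rad[p]
        out_rsib[k] = rad[sib]
        out_rterm[k] = rad[term]
        # restore parent row
        xd[p, 0], xd[p, 1], xd[p, 2] = sxd0, sxd1, sxd2
        left[p] = sl
        right[p] = sr


_F = ("cv", "cp", "cd", "v_ref", "l_ref", "r_ref", "gamma_f")


class GrowthEngine:
    """Structure-of-arrays mirror of a tree, for fast candidate evaluation."""

    def __init__(self, tree, cost, frozen_flows=None, allowed_ids=None):
        """``frozen_flows`` maps terminal vessel id -> fixed outflow; remaining
        (free) terminals share the remaining inlet flow equally.  ``allowed_ids``
        restricts which existing vessels may be split (default: all)."""
        self.tree = tree
        self.cost_params = (
            float(cost.c_v), float(cost.c_p), float(cost.c_d),
            float(cost.V_ref), float(cost.l_ref), float(cost.r_ref),
            float(cost.gamma),
        )
        self.gamma = float(tree.gamma)
        self.r0 = float(tree.r0)
        self.Q_in = float(tree.Q_in)
        frozen_flows = dict(frozen_flows or {})
        n = len(tree.vessels)
        cap = max(2 * n + 4, 64)
        self._alloc(cap)
        self.row_of: dict[int, int] = {}
        self.row_id = np.full(cap, -1, dtype=np.int64)
        for row, v in enumerate(tree.pre_order()):
            self.row_of[v.id] = row
            self.row_id[row] = v.id
        for v in tree.vessels.values():
            row = self.row_of[v.id]
            self.xp[row] = v.x_p
            self.xd[row] = v.x_d
            self.mu[row] = v.mu
            if v.is_terminal:
                self.left[row] = -1
                self.right[row] = -1
                if v.id in frozen_flows:
                    self.frozen[row] = 1
                    self.qfix[row] = frozen_flows[v.id]
            else:
                self.left[row] = self.row_of[v.children[0]]
                self.right[row] = self.row_of[v.children[1]]
            self.parent[row] = -1 if v.parent is None else self.row_of[v.parent]
        self.n = n
        self.root = self.row_of[tree.root_id]
        self.fr_sum = float(sum(frozen_flows.values()))
        self.n_free = sum(
            1 for v in tree.vessels.values()
            if v.is_terminal and v.id not in frozen_flows
        )
        if self.n_free < 1:
            raise ValueError("at least one free terminal is required")
        if self.Q_in - self.fr_sum <= 0:
            raise ValueError("frozen outflows leave no positive remaining flow")
        self.allowed = np.zeros(cap, dtype=np.uint8)
        if allowed_ids is None:
            self.allowed[:n] = 1
        else:
            for vid in allowed_ids:
                self.allowed[self.row_of[vid]] = 1
        self.refresh()

    def _alloc(self, cap):
        self.parent = np.full(cap, -1, dtype=np.int64)
        self.left = np.full(cap, -1, dtype=np.int64)
        self.right = np.full(cap, -1, dtype=np.int64)
        self.xp = np.zeros((cap, 3))
        self.xd = np.zeros((cap, 3))
        self.mu = np.zeros(cap)
        self.frozen = np.zeros(cap, dtype=np.uint8)
        self.qfix = np.zeros(cap)
        self.Q = np.zeros(cap)
        self.rstar = np.zeros(cap)
        self.beta = np.zeros(cap)
        self.acc_a = np.zeros(cap)
        self.acc_b = np.zeros(cap)
        self.rad = np.zeros(cap)
        self._post2 = np.zeros(cap, dtype=np.int64)

    def _grow_capacity(self):
        cap = 2 * len(self.mu)
        old = dict(self.__dict__)
        self._alloc(cap)
        for name in ("parent", "left", "right", "mu", "frozen", "qfix",
                     "Q", "rstar", "beta", "acc_a", "acc_b", "rad"):
            getattr(self, name)[: self.n] = old[name][: self.n]
        self.xp[: self.n] = old["xp"][: self.n]
        self.xd[: self.n] = old["xd"][: self.n]
        new_row_id = np.full(cap, -1, dtype=np.int64)
        new_row_id[: self.n] = self.row_id[: self.n]
        self.row_id = new_row_id
        new_allowed = np.zeros(cap, dtype=np.uint8)
        new_allowed[: self.n] = old["allowed"][: self.n]
        self.allowed = new_allowed

    # ------------------------------------------------------------------ state
    @property
    def q_free(self) -> float:
        return (self.Q_in - self.fr_sum) / self.n_free

    def refresh(self):
        """Recompute post-order, flows, betas, radii and the base cost."""
        self.post = _postorder(self.left, self.right, self.root, self.n)
        self.pos_in_post = np.empty(self.n, dtype=np.int64)
        self.pos_in_post[self.post] = np.arange(self.n)
        self._recompute()

    def _recompute(self):
        """Re-evaluate flows/betas/radii/cost on the current topology (also
        restores the scratch arrays after candidate evaluation)."""
        cv, cp_, cd, v_ref, l_ref, r_ref, gamma_f = self.cost_params
        self.base_cost = _eval_core(
            self.post, self.left, self.right, self.xp, self.xd, self.mu,
            self.frozen, self.qfix, self.q_free, self.gamma, gamma_f,
            cv, cp_, cd, v_ref, l_ref, r_ref, self.r0,
            self.Q, self.rstar, self.beta, self.acc_a, self.acc_b, self.rad,
        )

    def point_seg_dists(self, x) -> np.ndarray:
        out = np.empty(self.n)
        _point_seg_dists(np.asarray(x, dtype=float), self.xp, self.xd, self.n, out)
        return out

    def min_point_dist(self, x) -> float:
        return float(self.point_seg_dists(x).min())

    def neighbourhood_rows(self, x_new, count: int) -> np.ndarray:
        """Rows of the ``count`` allowed vessels closest to ``x_new``,
        ordered by (distance, vessel id)."""
        dists = self.point_seg_dists(x_new)
        rows = np.flatnonzero(self.allowed[: self.n] == 1)
        if len(rows) == 0:
            raise ValueError("no allowed parent vessels")
        order = np.lexsort((self.row_id[rows], dists[rows]))
        return rows[order[: max(1, count)]]

    def eval_candidates(self, cand_parent_rows, cand_bifs, x_new, mu_new):
        """Full-rescale cost and provisional radii for each candidate.

        Returns (cost, r_stub, r_sib, r_term, collision_ok) arrays; candidate
        free-terminal flow is the post-insertion homogeneous share.
        """
        k = len(cand_parent_rows)
        out_cost = np.empty(k)
        out_rstub = np.empty(k)
        out_rsib = np.empty(k)
        out_rterm = np.empty(k)
        if len(self.mu) < self.n + 2:
            self._grow_capacity()
        cv, cp_, cd, v_ref, l_ref, r_ref, gamma_f = self.cost_params
        q_free_new = (self.Q_in - self.fr_sum) / (self.n_free + 1)
        _eval_candidates(
            self.n, self.post, self.pos_in_post, self.parent, self.left,
            self.right, self.xp, self.xd, self.mu, self.frozen, self.qfix,
            q_free_new, self.gamma, gamma_f, cv, cp_, cd, v_ref, l_ref,
            r_ref, self.r0,
            np.asarray(cand_parent_rows, dtype=np.int64),
            np.asarray(cand_bifs, dtype=float),
            np.asarray(x_new, dtype=float), float(mu_new),
            self.Q, self.rstar, self.beta, self.acc_a, self.acc_b, self.rad,
            self._post2, out_cost, out_rstub, out_rsib, out_rterm,
        )
        self._recompute()  # scratch arrays hold the last candidate's state
        return out_cost, out_rstub, out_rsib, out_rterm

    def terminal_collision_free(self, parent_row: int, x_bif, x_new,
                                r_term: float) -> bool:
        """Sum-of-radii clearance of the would-be terminal segment against all
        non-adjacent vessels (current radii)."""
        return bool(_terminal_collision_free(
            self.n, int(parent_row), np.asarray(x_bif, dtype=float),
            np.asarray(x_new, dtype=float), self.xp, self.xd, self.rad,
            float(r_term),
        ))

    # ------------------------------------------------------------- mutation
    def apply_insertion(self, parent_row: int, x_bif, x_new,
                        stub_id: int, sibling_id: int, terminal_id: int,
                        mu_new: float):
        """Mirror an accepted split into the arrays and refresh the state."""
        if len(self.mu) < self.n + 2:
            self._grow_capacity()
        p = parent_row
        sib, term = self.n, self.n + 1
        self.xp[sib] = np.asarray(x_bif, dtype=float)
        self.xd[sib] = self.xd[p].copy()
        self.left[sib] = self.left[p]
        self.right[sib] = self.right[p]
        if self.left[p] != -1:
            self.parent[self.left[p]] = sib
            self.parent[self.right[p]] = sib
        self.frozen[sib] = self.frozen[p]
        self.qfix[sib] = self.qfix[p]
        self.mu[sib] = self.mu[p]
        self.parent[sib] = p
        self.xp[term] = np.asarray(x_bif, dtype=float)
        self.xd[term] = np.asarray(x_new, dtype=float)
        self.left[term] = -1
        self.right[term] = -1
        self.frozen[term] = 0
        self.qfix[term] = 0.0
        self.mu[term] = mu_new
        self.parent[term] = p
        self.xd[p] = np.asarray(x_bif, dtype=float)
        self.left[p] = sib
        self.right[p] = term
        self.frozen[p] = 0
        self.qfix[p] = 0.0
        self.allowed[sib] = self.allowed[p]
        self.allowed[term] = 1
        # id bookkeeping: stub reuses the parent's row
        old_id = self.row_id[p]
        del self.row_of[old_id]
        self.row_id[p] = stub_id
        self.row_of[stub_id] = p
        self.row_id[sib] = sibling_id
        self.row_of[sibling_id] = sib
        self.row_id[term] = terminal_id
        self.row_of[terminal_id] = term
        self.n += 2
        self.n_free += 1
        self.refresh()

    def sync_to_tree(self, tree):
        """Write radii, flows and viscosities back to the vessel objects."""
        for vid, row in self.row_of.items():
            v = tree.vessels[vid]
            v.r = float(self.rad[row])
            v.Q = float(self.Q[row])
            v.mu = float(self.mu[row])
            v.beta = float(self.beta[row])
            if v.is_terminal:
                v.q_out = float(
                    self.qfix[row] if self.frozen[row] == 1 else self.q_free
                )
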