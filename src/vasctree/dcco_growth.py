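"""Sequential constructive growth: cost functionals, candidate search and the
stage driver.

One terminal at a time, a random distal point is drawn in the perfusion
domain, connections to the nearest vessels are assayed over a lattice of
trial bifurcation points inside the triangle (parent proximal, parent distal,
new point), each provisional tree is fully rescaled, and the connection with
the smallest cost increment is kept, subject to geometric and haemodynamic
validity constraints.
"""

from __future__ import annotations

import dataclasses
import functools
import logging
import math
from fractions import Fraction

import numpy as np

from ._engine import GrowthEngine
from .domain_geometry import PerfusionDomain
from .hemodynamics import ConstantViscosity, ViscosityModel, fixed_point_viscosity_radii
from .vessel_tree import VascularTree, add_terminal, assign_terminal_flows

__all__ = [
    "CostFunctional",
    "StageConfig",
    "Insertion",
    "GrowthError",
    "vessel_cost",
    "tree_cost",
    "neighbourhood_size",
    "neighbourhood",
    "candidate_bifurcation_points",
    "is_valid_connection",
    "try_insert",
    "grow",
    "run_stages",
]

log = logging.getLogger(__name__)


class GrowthError(RuntimeError):
    """A terminal could not be placed within the configured attempt budget."""


@dataclasses.dataclass(frozen=True)
class CostFunctional:
    """Per-vessel cost; the tree cost is the sum over all segments.

    The sprouting form is
    ``c_v pi l r^(gamma-1) / V_ref^(gamma/3) + c_p r / r_ref + c_d (l/l_ref)^2``
    with ``c_v + c_p + c_d = 1``; with ``gamma = 3``, ``c_v = 1`` and unit
    references it reduces to the intravascular volume ``pi l r^2``.
    """

    kind: str = "volumetric"
    c_v: float = 1.0
    c_p: float = 0.0
    c_d: float = 0.0
    V_ref: float = 1.0
    l_ref: float = 1.0
    r_ref: float = 1.0
    gamma: float = 3.0

    def __post_init__(self):
        if self.kind not in ("volumetric", "sprouting"):
            raise ValueError(f"unknown cost functional kind: {self.kind}")
        if min(self.c_v, self.c_p, self.c_d) < 0:
            raise ValueError("cost coefficients must be non-negative")
        if abs(self.c_v + self.c_p + self.c_d - 1.0) > 1e-12:
            raise ValueError("cost coefficients must sum to 1")
        if min(self.V_ref, self.l_ref, self.r_ref) <= 0:
            raise ValueError("reference values must be positive")
        if self.kind == "volumetric" and (
            self.c_v != 1.0 or self.gamma != 3.0 or self.V_ref != 1.0
        ):
            raise ValueError("volumetric functional is the reduction case "
                             "(c_v=1, gamma=3, V_ref=1)")

    @classmethod
    def volumetric(cls) -> "CostFunctional":
        return cls(kind="volumetric")

    @classmethod
    def sprouting(cls, c_v, c_p, c_d, V_ref, l_ref, r_ref,
                  gamma: float = 3.0) -> "CostFunctional":
        return cls(kind="sprouting", c_v=c_v, c_p=c_p, c_d=c_d,
                   V_ref=V_ref, l_ref=l_ref, r_ref=r_ref, gamma=gamma)


def vessel_cost(v, F: CostFunctional) -> float:
    l = v.length
    return (F.c_v * math.pi * l * v.r ** (F.gamma - 1.0) / F.V_ref ** (F.gamma / 3.0)
            + F.c_p * v.r / F.r_ref
            + F.c_d * (l / F.l_ref) ** 2)


def tree_cost(tree: VascularTree | None, F: CostFunctional) -> float:
    if tree is None or len(tree.vessels) == 0:
        return 0.0
    return math.fsum(vessel_cost(v, F) for v in tree.vessels.values())


@dataclasses.dataclass
class StageConfig:
    """Parameters controlling one growth stage.

    ``f_n`` scales the searched neighbourhood (``round(f_n * M**(1/3))``
    closest vessels for an M-segment tree); ``n_bif`` is the number of trial
    bifurcation points per parent; ``f_r`` relaxes the minimum-distance
    criterion after batches of failed point draws; ``delta`` bounds daughter
    radius asymmetry; angles are in degrees.  ``opt_v`` is an accepted but
    unused knob kept for config compatibility.
    """

    N: int
    cost: CostFunctional = dataclasses.field(default_factory=CostFunctional.volumetric)
    name: str = "stage"
    domain: PerfusionDomain | None = None
    gamma: float = 3.0
    delta: float = 0.0
    f_r: float = 0.9
    f_n: float = 1.0
    n_bif: int = 7
    theta_min: float = 30.0
    phi_min: float = 0.0
    seed: int = 0
    k_d: float = 0.25
    n_inside_samples: int = 5
    max_attempts_per_terminal: int = 4000
    relax_floor: float = 1e-4
    opt_v: float = 1.0

    def __post_init__(self):
        if self.N < 0:
            raise ValueError("N must be non-negative")
        if self.n_bif < 1:
            raise ValueError("n_bif must be at least 1")
        if not 0.0 < self.f_r <= 1.0:
            raise ValueError("f_r must be in (0, 1]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class Insertion:
    """Winning candidate returned by :func:`try_insert`."""

    parent_id: int
    x_bif: np.ndarray
    x_new: np.ndarray
    dF: float
    candidate_index: int


# ---------------------------------------------------------------- candidates
def neighbourhood_size(n_segments: int, f_n: float) -> int:
    return max(1, round(f_n * n_segments ** (1.0 / 3.0)))


def neighbourhood(tree: VascularTree, x_new, f_n: float,
                  allowed_ids=None) -> list[int]:
    """Ids of the closest allowed vessels by point-to-segment distance,
    ordered by (distance, id)."""
    engine = GrowthEngine(tree, CostFunctional.volumetric(),
                          allowed_ids=allowed_ids)
    rows = engine.neighbourhood_rows(
        np.asarray(x_new, dtype=float),
        neighbourhood_size(tree.n_segments, f_n),
    )
    return [int(engine.row_id[r]) for r in rows]


@functools.lru_cache(maxsize=None)
def _barycentric_lattice(n_bif: int) -> np.ndarray:
    """First ``n_bif`` interior lattice weights (centroid first), deduplicated
    across subdivision levels, as an (n_bif, 3) float array."""
    weights: list[tuple[Fraction, Fraction, Fraction]] = []
    seen: set[tuple[Fraction, Fraction, Fraction]] = set()
    m = 3
    while len(weights) < n_bif:
        for i in range(1, m - 1):
            for j in range(1, m - i):
                k = m - i - j
                w = (Fraction(i, m), Fraction(j, m), Fraction(k, m))
                if w not in seen:
                    seen.add(w)
                    weights.append(w)
        m += 1
    return np.array([[float(x) for x in w] for w in weights[:n_bif]])


def candidate_bifurcation_points(x_pp, x_pd, x_new, n_bif: int) -> np.ndarray:
    """Deterministic barycentric lattice of points strictly inside the
    triangle (parent proximal, parent distal, new distal); the centroid comes
    first.  Returns an empty (0, 3) array for a degenerate triangle."""
    a = np.asarray(x_pp, dtype=float)
    b = np.asarray(x_pd, dtype=float)
    c = np.asarray(x_new, dtype=float)
    area2 = np.linalg.norm(np.cross(b - a, c - a))
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a)) ** 2
    if area2 <= 1e-10 * scale or scale == 0.0:
        return np.empty((0, 3))
    return _barycentric_lattice(n_bif) @ np.vstack([a, b, c])


def _angle_deg(u, v) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return math.degrees(math.acos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)))


def _segment_inside(domain: PerfusionDomain, a, b, n_samples: int) -> bool:
    t = (np.arange(1, n_samples + 1) / (n_samples + 1.0))[:, None]
    pts = np.asarray(a, dtype=float)[None, :] * (1 - t) + np.asarray(b, dtype=float)[None, :] * t
    return bool(domain.contains_many(pts).all())


def _segments_inside_many(domain: PerfusionDomain, starts: np.ndarray,
                          ends: np.ndarray, n_samples: int) -> np.ndarray:
    """Per-segment flag: all interior sample points inside the domain."""
    k = len(starts)
    t = np.arange(1, n_samples + 1) / (n_samples + 1.0)
    pts = (starts[:, None, :] * (1 - t)[None, :, None]
           + ends[:, None, :] * t[None, :, None])
    inside = domain.contains_many(pts.reshape(k * n_samples, 3))
    return inside.reshape(k, n_samples).all(axis=1)


def _angles_deg_many(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    denom = np.where((nu > 0) & (nv > 0), nu * nv, 1.0)
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / denom, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _seg_seg_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two segments (pure-python reference)."""
    p0, p1, q0, q1 = (np.asarray(x, dtype=float) for x in (p0, p1, q0, q1))
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    den = a * c - b * b
    s = (b * e - c * d) / den if den > 1e-14 * max(a * c, 1e-300) else 0.0
    s = min(max(s, 0.0), 1.0)
    t = (b * s + e) / c if c > 0 else 0.0
    t = min(max(t, 0.0), 1.0)
    if a > 0:
        s = min(max((b * t - d) / a, 0.0), 1.0)
    return float(np.linalg.norm(w + s * u - t * v))


def is_valid_connection(tree: VascularTree, parent_id: int, x_bif, x_new,
                        stage: StageConfig, domain: PerfusionDomain,
                        frozen: dict[int, float] | None = None,
                        ) -> tuple[bool, str]:
    """Reference validity check for one candidate connection.

    Builds the provisional tree explicitly (object model), rescales it, and
    applies all constraints; returns ``(ok, reason)`` where reason is one of
    ``ok, degenerate-triangle, outside-domain, angle, symmetry, collision,
    aspect``.
    """
    parent = tree.vessels[parent_id]
    x_bif = np.asarray(x_bif, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    area2 = np.linalg.norm(np.cross(parent.x_d - parent.x_p, x_new - parent.x_p))
    if area2 <= 1e-10 * max(parent.length, np.linalg.norm(x_new - parent.x_p)) ** 2:
        return False, "degenerate-triangle"
    n_s = stage.n_inside_samples
    parent_inside = _segment_inside(domain, parent.x_p, parent.x_d, n_s)
    if not _segment_inside(domain, x_bif, x_new, n_s):
        return False, "outside-domain"
    if parent_inside and not (
        _segment_inside(domain, parent.x_p, x_bif, n_s)
        and _segment_inside(domain, x_bif, parent.x_d, n_s)
    ):
        return False, "outside-domain"
    u_sib = parent.x_d - x_bif
    u_term = x_new - x_bif
    w_par = x_bif - parent.x_p
    if _angle_deg(u_sib, u_term) < stage.theta_min:
        return False, "angle"
    if stage.phi_min > 0 and (
        _angle_deg(w_par, u_sib) < stage.phi_min
        or _angle_deg(w_par, u_term) < stage.phi_min
    ):
        return False, "angle"
    # provisional tree for radius-dependent checks
    trial = tree.copy()
    stub_id, sib_id, term_id = add_terminal(trial, parent_id, x_bif, x_new)
    assign_terminal_flows(trial, fixed=frozen)
    from .vessel_tree import rescale_radii

    rescale_radii(trial)
    r_sib = trial.vessels[sib_id].r
    r_term = trial.vessels[term_id].r
    if min(r_sib, r_term) / max(r_sib, r_term) < stage.delta:
        return False, "symmetry"
    for vid in (stub_id, sib_id, term_id):
        v = trial.vessels[vid]
        if v.length < 2.0 * v.r:
            return False, "aspect"
    # clearance against the pre-insertion geometry (current radii), skipping
    # the split parent which shares the bifurcation point
    term = trial.vessels[term_id]
    for v in tree.vessels.values():
        if v.id == parent_id:
            continue
        if _seg_seg_distance(term.x_p, term.x_d, v.x_p, v.x_d) < term.r + v.r:
            return False, "collision"
    return True, "ok"


# ------------------------------------------------------------------ insertion
def _try_insert_engine(engine: GrowthEngine, x_new, stage: StageConfig,
                       domain: PerfusionDomain):
    """Best valid insertion for one distal point, using the array engine.

    Returns ``(parent_row, x_bif, dF, candidate_index)`` or ``None``.
    """
    x_new = np.asarray(x_new, dtype=float)
    rows = engine.neighbourhood_rows(
        x_new, neighbourhood_size(engine.n, stage.f_n)
    )
    n_s = stage.n_inside_samples
    cand_rows: list[int] = []
    cand_bifs: list[np.ndarray] = []
    cand_idx: list[int] = []
    x_new_tiled = None
    for row in rows:
        xp_p, xd_p = engine.xp[row], engine.xd[row]
        bifs = candidate_bifurcation_points(xp_p, xd_p, x_new, stage.n_bif)
        if len(bifs) == 0:
            continue
        if x_new_tiled is None or len(x_new_tiled) != len(bifs):
            x_new_tiled = np.broadcast_to(x_new, (len(bifs), 3))
        u_sib = xd_p[None, :] - bifs
        u_term = x_new_tiled - bifs
        ok = _angles_deg_many(u_sib, u_term) >= stage.theta_min
        if stage.phi_min > 0:
            u_par = bifs - xp_p[None, :]
            ok &= _angles_deg_many(u_par, u_sib) >= stage.phi_min
            ok &= _angles_deg_many(u_par, u_term) >= stage.phi_min
        if ok.any():
            ok &= _segments_inside_many(domain, bifs, np.asarray(x_new_tiled), n_s)
        if ok.any() and _segment_inside(domain, xp_p, xd_p, n_s):
            xp_tiled = np.broadcast_to(xp_p, (len(bifs), 3))
            xd_tiled = np.broadcast_to(xd_p, (len(bifs), 3))
            ok &= _segments_inside_many(domain, np.asarray(xp_tiled), bifs, n_s)
            ok &= _segments_inside_many(domain, bifs, np.asarray(xd_tiled), n_s)
        for i in np.flatnonzero(ok):
            cand_rows.append(int(row))
            cand_bifs.append(bifs[i])
            cand_idx.append(int(i))
    if not cand_rows:
        return None
    # new vessels inherit the growth viscosity of the first candidate parent
    mu_new = float(engine.mu[cand_rows[0]])
    costs, r_stub, r_sib, r_term, = engine.eval_candidates(
        np.array(cand_rows), np.array(cand_bifs), x_new, mu_new
    )
    # rank by (dF, parent id, candidate index), then probe the expensive
    # collision check in that order until one candidate is clear
    ranked = []
    for k in range(len(cand_rows)):
        if not (np.isfinite(costs[k]) and r_term[k] > 0):
            continue
        lo, hi = min(r_sib[k], r_term[k]), max(r_sib[k], r_term[k])
        if lo / hi < stage.delta:
            continue
        bif = cand_bifs[k]
        l_stub = np.linalg.norm(bif - engine.xp[cand_rows[k]])
        l_sib = np.linalg.norm(engine.xd[cand_rows[k]] - bif)
        l_term = np.linalg.norm(x_new - bif)
        if (l_stub < 2 * r_stub[k] or l_sib < 2 * r_sib[k]
                or l_term < 2 * r_term[k]):
            continue
        dF = costs[k] - engine.base_cost
        ranked.append(((dF, int(engine.row_id[cand_rows[k]]), cand_idx[k]), k))
    ranked.sort(key=lambda item: item[0])
    for key, k in ranked:
        if engine.terminal_collision_free(cand_rows[k], cand_bifs[k], x_new,
                                          r_term[k]):
            return cand_rows[k], np.asarray(cand_bifs[k]), float(key[0]), cand_idx[k]
    return None


def try_insert(tree: VascularTree, x_new, stage: StageConfig,
               domain: PerfusionDomain,
               frozen: dict[int, float] | None = None,
               allowed_ids=None) -> Insertion | None:
    """Best insertion of a terminal at ``x_new``, or ``None`` if no candidate
    is valid.  Ties in the cost increment break on (parent id, candidate
    index)."""
    engine = GrowthEngine(tree, stage.cost, frozen_flows=frozen,
                          allowed_ids=allowed_ids)
    hit = _try_insert_engine(engine, x_new, stage, domain)
    if hit is None:
        return None
    row, x_bif, dF, idx = hit
    return Insertion(parent_id=int(engine.row_id[row]), x_bif=x_bif,
                     x_new=np.asarray(x_new, dtype=float), dF=dF,
                     candidate_index=idx)


# ---------------------------------------------------------------------- grow
def grow(tree: VascularTree, domain: PerfusionDomain, stage: StageConfig,
         *, sample_domain: PerfusionDomain | None = None,
         frozen: dict[int, float] | None = None,
         allowed_ids=None,
         records: list | None = None,
         rng: np.random.Generator | None = None,
         viscosity_model: ViscosityModel | None = None,
         final_pass: bool = True) -> VascularTree:
    """Add ``stage.N`` terminals to ``tree`` inside ``sample_domain`` (defaults
    to ``domain``); validity of new segments is checked against ``domain``.

    ``frozen`` fixes outflows of listed terminals; the remaining flow is
    redistributed homogeneously over the other (free) terminals as the tree
    grows.  ``allowed_ids`` restricts the initially splittable vessels;
    vessels created during this call are always splittable.  Each insertion is
    appended to ``records`` as ``(x_new, x_bif, parent_x_p, parent_x_d)``
    coordinate tuples when a list is given.  Deterministic for a given
    ``stage.seed``.
    """
    if stage.N == 0:
        return tree
    where = sample_domain if sample_domain is not None else domain
    rng = rng if rng is not None else np.random.default_rng(stage.seed)
    engine = GrowthEngine(tree, stage.cost, frozen_flows=frozen,
                          allowed_ids=allowed_ids)
    volume = where.volume
    added = 0
    failures = 0
    relax = 1.0
    attempts = 0
    budget = stage.max_attempts_per_terminal
    while added < stage.N:
        if attempts >= budget:
            raise GrowthError(
                f"failed to place terminal {added + 1}/{stage.N} after "
                f"{attempts} attempts (relaxation {relax:.3g})"
            )
        attempts += 1
        x_new = where.sample_point(rng)
        n_term = (engine.n + 1) // 2
        d_crit = stage.k_d * (volume / (n_term + 1)) ** (1.0 / 3.0) * relax
        accepted = False
        if engine.min_point_dist(x_new) >= d_crit:
            hit = _try_insert_engine(engine, x_new, stage, domain)
            if hit is not None:
                row, x_bif, dF, _ = hit
                parent_id = int(engine.row_id[row])
                parent_xp = engine.xp[row].copy()
                parent_xd = engine.xd[row].copy()
                mu_new = float(engine.mu[row])
                stub_id, sib_id, term_id = add_terminal(
                    tree, parent_id, x_bif, x_new, stage=stage.name
                )
                engine.apply_insertion(row, x_bif, x_new, stub_id, sib_id,
                                       term_id, mu_new)
                if records is not None:
                    records.append((x_new.copy(), x_bif.copy(),
                                    parent_xp, parent_xd))
                added += 1
                failures = 0
                relax = 1.0
                attempts = 0
                log.debug("placed terminal %d/%d (dF=%.3g, parent=%d)",
                          added, stage.N, dF, parent_id)
                accepted = True
        if not accepted:
            failures += 1
            if failures % 10 == 0:
                relax *= stage.f_r
                if relax < stage.relax_floor:
                    raise GrowthError(
                        f"distance relaxation hit the floor ({relax:.3g}) "
                        f"while placing terminal {added + 1}/{stage.N}"
                    )
    engine.sync_to_tree(tree)
    assign_terminal_flows(tree, fixed=frozen)
    if final_pass:
        model = viscosity_model if viscosity_model is not None else ConstantViscosity()
        fixed_point_viscosity_radii(tree, model)
    log.info("stage %s: added %d terminals (%d segments total)",
             stage.name, added, tree.n_segments)
    return tree


def run_stages(tree: VascularTree, stages: list[StageConfig],
               domain: PerfusionDomain | None = None,
               viscosity_model: ViscosityModel | None = None) -> VascularTree:
    """Apply growth stages in order; each stage receives the previous output.

    A stage uses its own ``stage.domain`` when set, else ``domain``.
    """
    for stage in stages:
        dom = stage.domain if stage.domain is not None else domain
        if dom is None:
            raise ValueError(f"stage {stage.name!r} has no domain")
        tree = grow(tree, dom, stage, viscosity_model=viscosity_model)
    return tree
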