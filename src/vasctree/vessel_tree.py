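"""Binary vessel-tree data model: topology edits, flow bookkeeping, radius scaling.

The tree is a rooted strict binary tree of rigid cylindrical segments.  A tree
with ``N`` terminals always has ``2N - 1`` segments.  Radii obey the branching
power law ``r_p**gamma = r_l**gamma + r_r**gamma`` after
:func:`rescale_radii`, whose closure equalizes terminal pressures through the
classic reduced-resistance recurrence.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterator

import numpy as np

__all__ = [
    "Vessel",
    "VascularTree",
    "add_terminal",
    "assign_terminal_flows",
    "rescale_radii",
    "generation_of",
    "DEFAULT_MU_POISE",
]

#: default effective viscosity, poise (3.6 cP)
DEFAULT_MU_POISE = 0.036


@dataclasses.dataclass
class Vessel:
    """One rigid cylindrical segment."""

    id: int
    x_p: np.ndarray
    x_d: np.ndarray
    r: float
    parent: int | None = None
    children: tuple[int, ...] = ()
    beta: float = 1.0
    Q: float = 0.0
    mu: float = DEFAULT_MU_POISE
    q_out: float = 0.0
    n_term_sub: int = 1
    stage: str = ""

    def __post_init__(self):
        self.x_p = np.asarray(self.x_p, dtype=float)
        self.x_d = np.asarray(self.x_d, dtype=float)
        if self.r <= 0:
            raise ValueError(f"vessel {self.id}: radius must be positive")
        if self.length <= 0:
            raise ValueError(f"vessel {self.id}: zero-length segment")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.x_d - self.x_p))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.x_p + self.x_d)

    @property
    def is_terminal(self) -> bool:
        return len(self.children) == 0


class VascularTree:
    """Rooted binary tree of vessels plus inlet boundary data.

    Parameters
    ----------
    gamma : branching power-law exponent.
    Q_in : inlet flow rate, cm^3/s.
    r0 : fixed root radius, cm.
    """

    def __init__(self, gamma: float = 3.0, Q_in: float = 1.0, r0: float = 0.1):
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        if Q_in <= 0 or r0 <= 0:
            raise ValueError("inlet flow and root radius must be positive")
        self.gamma = float(gamma)
        self.Q_in = float(Q_in)
        self.r0 = float(r0)
        self.vessels: dict[int, Vessel] = {}
        self.root_id: int | None = None
        self._next_id = 0
        #: retired-id -> replacing stub id, kept for record replay
        self.id_aliases: dict[int, int] = {}

    # ------------------------------------------------------------------ build
    @classmethod
    def from_root(cls, x_p, x_d, r0: float, Q_in: float,
                  gamma: float = 3.0) -> "VascularTree":
        tree = cls(gamma=gamma, Q_in=Q_in, r0=r0)
        root = Vessel(id=tree._take_id(), x_p=x_p, x_d=x_d, r=r0, Q=Q_in,
                      q_out=Q_in)
        tree.vessels[root.id] = root
        tree.root_id = root.id
        return tree

    def _take_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    # ------------------------------------------------------------ inspection
    @property
    def root(self) -> Vessel:
        return self.vessels[self.root_id]

    def __len__(self) -> int:
        return len(self.vessels)

    @property
    def n_segments(self) -> int:
        return len(self.vessels)

    @property
    def n_terminals(self) -> int:
        return sum(1 for v in self.vessels.values() if v.is_terminal)

    def terminal_ids(self) -> list[int]:
        return [v.id for v in self.vessels.values() if v.is_terminal]

    def post_order(self) -> Iterator[Vessel]:
        """Children-before-parent traversal (iterative, no recursion limit)."""
        stack = [(self.root_id, False)]
        while stack:
            vid, done = stack.pop()
            if done:
                yield self.vessels[vid]
            else:
                stack.append((vid, True))
                for c in reversed(self.vessels[vid].children):
                    stack.append((c, False))

    def pre_order(self) -> Iterator[Vessel]:
        stack = [self.root_id]
        while stack:
            v = self.vessels[stack.pop()]
            yield v
            for c in reversed(v.children):
                stack.append(c)

    def path_to_root(self, vessel_id: int) -> list[int]:
        path = [vessel_id]
        while self.vessels[path[-1]].parent is not None:
            path.append(self.vessels[path[-1]].parent)
        return path

    def resolve_id(self, vessel_id: int) -> int:
        """Follow stub aliases of retired ids to the live vessel."""
        while vessel_id not in self.vessels:
            vessel_id = self.id_aliases[vessel_id]
        return vessel_id

    def copy(self) -> "VascularTree":
        out = VascularTree(gamma=self.gamma, Q_in=self.Q_in, r0=self.r0)
        out.root_id = self.root_id
        out._next_id = self._next_id
        out.id_aliases = dict(self.id_aliases)
        for vid, v in self.vessels.items():
            out.vessels[vid] = dataclasses.replace(
                v, x_p=v.x_p.copy(), x_d=v.x_d.copy(), children=tuple(v.children)
            )
        return out

    # --------------------------------------------------------------- checks
    def validate(self) -> None:
        """Structural sanity: one root, 0/2 children, acyclic, 2N-1 law."""
        roots = [v for v in self.vessels.values() if v.parent is None]
        if len(roots) != 1 or roots[0].id != self.root_id:
            raise ValueError("tree must have exactly one root")
        seen = 0
        for v in self.post_order():
            seen += 1
            if len(v.children) not in (0, 2):
                raise ValueError(f"vessel {v.id} has {len(v.children)} children")
            for c in v.children:
                if self.vessels[c].parent != v.id:
                    raise ValueError(f"broken parent link at {c}")
        if seen != len(self.vessels):
            raise ValueError("unreachable vessels present (cycle or orphan)")
        if self.n_segments != 2 * self.n_terminals - 1:
            raise ValueError("segment count violates 2N-1 law")

    def recount_subtended(self) -> dict[int, int]:
        """Independent recount of subtended terminals by full traversal."""
        counts: dict[int, int] = {}
        for v in self.post_order():
            counts[v.id] = 1 if v.is_terminal else sum(
                counts[c] for c in v.children
            )
        return counts


def add_terminal(tree: VascularTree, parent_id: int, x_bif, x_new,
                 stage: str = "") -> tuple[int, int, int]:
    """Split ``parent_id`` at ``x_bif`` and attach a new terminal to ``x_new``.

    The parent segment ``x_p -> x_d`` is replaced by a proximal stub
    ``x_p -> x_bif`` (fresh id; the old id is retired and aliased to it), a
    sibling ``x_bif -> x_d`` inheriting the parent's children, and the new
    terminal ``x_bif -> x_new``.

    Returns ``(stub_id, sibling_id, terminal_id)``.
    """
    if parent_id not in tree.vessels:
        raise KeyError(f"unknown parent vessel {parent_id}")
    x_bif = np.asarray(x_bif, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    parent = tree.vessels[parent_id]
    for endpoint in (parent.x_p, parent.x_d):
        if np.array_equal(x_bif, endpoint):
            raise ValueError("bifurcation point coincides with a parent endpoint")
    if np.array_equal(x_new, x_bif):
        raise ValueError("new distal point coincides with the bifurcation")

    stub = Vessel(id=tree._take_id(), x_p=parent.x_p.copy(), x_d=x_bif.copy(),
                  r=parent.r, parent=parent.parent, mu=parent.mu,
                  n_term_sub=parent.n_term_sub + 1, stage=parent.stage)
    sibling = Vessel(id=tree._take_id(), x_p=x_bif.copy(), x_d=parent.x_d.copy(),
                     r=parent.r, parent=stub.id, children=tuple(parent.children),
                     mu=parent.mu, n_term_sub=parent.n_term_sub,
                     q_out=parent.q_out, stage=parent.stage)
    terminal = Vessel(id=tree._take_id(), x_p=x_bif.copy(), x_d=x_new.copy(),
                      r=parent.r, parent=stub.id, mu=parent.mu, stage=stage)
    stub.children = (sibling.id, terminal.id)

    for c in parent.children:
        tree.vessels[c].parent = sibling.id
    del tree.vessels[parent_id]
    tree.id_aliases[parent_id] = stub.id
    tree.vessels[stub.id] = stub
    tree.vessels[sibling.id] = sibling
    tree.vessels[terminal.id] = terminal

    if parent.parent is None:
        tree.root_id = stub.id
    else:
        gp = tree.vessels[parent.parent]
        gp.children = tuple(stub.id if c == parent_id else c for c in gp.children)
        anc = parent.parent
        while anc is not None:
            tree.vessels[anc].n_term_sub += 1
            anc = tree.vessels[anc].parent
    return stub.id, sibling.id, terminal.id


def assign_terminal_flows(tree: VascularTree,
                          fixed: dict[int, float] | None = None) -> VascularTree:
    """Set terminal outflows and propagate flows bottom-up.

    With ``fixed=None`` every terminal receives ``Q_in / N_term``.  Otherwise
    the listed terminals keep their given outflow and the remaining flow is
    split homogeneously among the other terminals.
    """
    terminals = tree.terminal_ids()
    fixed = dict(fixed or {})
    for tid in fixed:
        if tid not in tree.vessels or not tree.vessels[tid].is_terminal:
            raise KeyError(f"fixed outflow refers to non-terminal vessel {tid}")
    free = [t for t in terminals if t not in fixed]
    q_fixed_total = math.fsum(fixed.values())
    q_part = tree.Q_in - q_fixed_total
    if free:
        if q_part <= 0:
            raise ValueError(
                f"remaining flow Q_part={q_part} is not positive"
            )
        q_free = q_part / len(free)
    else:
        q_free = 0.0
        if abs(q_part) > 1e-12 * tree.Q_in:
            raise ValueError("fixed outflows do not sum to the inlet flow")
    for tid in terminals:
        tree.vessels[tid].q_out = fixed.get(tid, q_free)
    for v in tree.post_order():
        v.Q = v.q_out if v.is_terminal else math.fsum(
            tree.vessels[c].Q for c in v.children
        )
    return tree


def reduced_resistances(tree: VascularTree) -> dict[int, float]:
    """Subtree reduced resistance at unit subtree-root radius (CGS, r = 1).

    ``R*_i = 8 mu_i l_i / pi + (beta_l^4 / R*_l + beta_r^4 / R*_r)^-1`` with
    beta factors from the equal-terminal-pressure closure; a side effect is
    that ``vessel.beta`` is updated for every non-root vessel.
    """
    gamma = tree.gamma
    rstar: dict[int, float] = {}
    for v in tree.post_order():
        r_unit = 8.0 * v.mu * v.length / math.pi
        if v.is_terminal:
            rstar[v.id] = r_unit
            continue
        cl, cr = (tree.vessels[c] for c in v.children)
        num = cr.Q * rstar[cr.id]
        den = cl.Q * rstar[cl.id]
        if not (num > 0 and den > 0) or not math.isfinite(num / den):
            raise ValueError(f"non-finite resistance below vessel {v.id}")
        xi = (num / den) ** 0.25  # r_r / r_l
        beta_l = (1.0 + xi ** gamma) ** (-1.0 / gamma)
        beta_r = (1.0 + xi ** (-gamma)) ** (-1.0 / gamma)
        cl.beta, cr.beta = beta_l, beta_r
        rstar[v.id] = r_unit + 1.0 / (
            beta_l ** 4 / rstar[cl.id] + beta_r ** 4 / rstar[cr.id]
        )
    return rstar


def rescale_radii(tree: VascularTree) -> VascularTree:
    """Propagate absolute radii from the fixed root radius through the betas.

    Requires flows to be assigned.  After the pass the branching law
    ``r_p**gamma = r_l**gamma + r_r**gamma`` holds exactly and daughter radius
    ratios satisfy the equal-terminal-pressure closure
    ``(r_l/r_r)**4 = (Q_l R*_l) / (Q_r R*_r)``.
    """
    reduced_resistances(tree)
    root = tree.root
    root.beta = 1.0
    root.r = tree.r0
    for v in tree.pre_order():
        if v.parent is not None:
            v.r = v.beta * tree.vessels[v.parent].r
    return tree


def generation_of(tree: VascularTree, vessel_id: int) -> int:
    """Number of bifurcations between the root and this vessel.

    In a finished strict binary tree every internal node bifurcates, so the
    generation equals the depth: the root is 0, both its daughters 1, etc.
    A proximal stub created by a split keeps its position on the path and
    therefore the original generation.
    """
    if vessel_id not in tree.vessels:
        raise KeyError(f"unknown vessel {vessel_id}")
    return len(tree.path_to_root(vessel_id)) - 1
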