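"""Partitioned concurrent tree growth and consistent merge.

From a sequentially grown baseline tree, each subdomain of a disjoint
partition is vascularized independently (the baseline vessels whose midpoint
falls inside the subdomain are the only pre-existing vessels allowed to
bifurcate there, and terminal outflows outside the subdomain stay frozen).
Every insertion is logged as a coordinate tuple; the merged tree replays the
logs against the baseline with an exact-coordinate lookup and is rescaled
once at the end.  Because subdomain parent sets are disjoint, the replay
result does not depend on whether subdomains were grown serially or
concurrently.
"""

from __future__ import annotations

import concurrent.futures
import dataclasses
import logging

import numpy as np

from .dcco_growth import StageConfig, grow
from .domain_geometry import DomainPartition, PerfusionDomain
from .hemodynamics import ConstantViscosity, ViscosityModel, fixed_point_viscosity_radii
from .vessel_tree import VascularTree, add_terminal, assign_terminal_flows

__all__ = [
    "InsertionRecord",
    "PipelineResult",
    "MergeError",
    "partition_parents",
    "subdomain_flow_conditions",
    "grow_subdomain",
    "merge",
    "pdcco_pipeline",
    "merged_terminal_count",
    "split_counts",
]

log = logging.getLogger(__name__)


class MergeError(RuntimeError):
    """A replayed record did not resolve to a live parent segment."""


@dataclasses.dataclass(frozen=True)
class InsertionRecord:
    """One logged insertion: where the terminal went and who was split."""

    x_new: np.ndarray
    x_bif: np.ndarray
    parent_x_p: np.ndarray
    parent_x_d: np.ndarray
    sequence: int
    subdomain: int

    def parent_key(self) -> tuple:
        return tuple(self.parent_x_p) + tuple(self.parent_x_d)


def merged_terminal_count(n_base: int, n_added: list[int]) -> int:
    """Terminal count of the merged network: baseline plus per-subdomain sums."""
    return int(n_base) + int(sum(int(n) for n in n_added))


def split_counts(total: int, n_part: int) -> list[int]:
    """Quotient/remainder split of ``total`` additions over ``n_part``
    subdomains (the remainder goes to the last one)."""
    if n_part < 1:
        raise ValueError("n_part must be positive")
    q, r = divmod(int(total), n_part)
    return [q] * (n_part - 1) + [q + r]


def partition_parents(tree: VascularTree, partition: DomainPartition,
                      index: int) -> set[int]:
    """Ids of vessels whose midpoint is labelled inside subdomain ``index``."""
    out = {
        v.id for v in tree.vessels.values()
        if partition.label(v.midpoint) == index
    }
    if not out:
        raise ValueError(
            f"subdomain {index} contains no baseline vessel midpoint; "
            "it cannot be grown"
        )
    return out


def subdomain_flow_conditions(tree: VascularTree, partition: DomainPartition,
                              index: int) -> tuple[dict[int, float], list[int]]:
    """Frozen outflows for terminals outside subdomain ``index`` and the list
    of free (inside) terminals that share the remaining flow."""
    v_part = {
        v.id for v in tree.vessels.values()
        if partition.label(v.midpoint) == index
    }
    frozen: dict[int, float] = {}
    free: list[int] = []
    for tid in tree.terminal_ids():
        if tid in v_part:
            free.append(tid)
        else:
            frozen[tid] = tree.vessels[tid].q_out
    q_part = tree.Q_in - sum(frozen.values())
    if q_part <= 0:
        raise ValueError(
            f"subdomain {index}: remaining flow Q_part={q_part} is not positive"
        )
    return frozen, free


def grow_subdomain(tree_base: VascularTree, partition: DomainPartition,
                   index: int, stage: StageConfig, seed: int = 0,
                   ) -> tuple[VascularTree, list[InsertionRecord]]:
    """Grow ``stage.N`` terminals inside one subdomain from the shared baseline.

    Works on a private copy of the baseline; candidate points are sampled in
    the subdomain, validity is checked against the full parent domain, only
    midpoint-resident baseline vessels (plus vessels created here) may split,
    and outside terminal outflows stay frozen.  The random stream derives
    from ``(seed, index)``.
    """
    v_part = partition_parents(tree_base, partition, index)
    frozen, _free = subdomain_flow_conditions(tree_base, partition, index)
    tree = tree_base.copy()
    raw: list = []
    if stage.N > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))
        grow(tree, partition.parent, stage,
             sample_domain=partition.subdomains[index],
             frozen=frozen, allowed_ids=v_part, records=raw, rng=rng)
    records = [
        InsertionRecord(x_new=xn, x_bif=xb, parent_x_p=pp, parent_x_d=pd,
                        sequence=i, subdomain=index)
        for i, (xn, xb, pp, pd) in enumerate(raw)
    ]
    return tree, records


def merge(tree_base: VascularTree, record_lists: list[list[InsertionRecord]],
          viscosity_model: ViscosityModel | None = None,
          rescale: bool = True) -> VascularTree:
    """Replay subdomain insertion logs onto the baseline tree.

    Records are applied list by list (ascending subdomain index), each in its
    logged order.  Parents are located by their exact (x_p, x_d) coordinates
    in a lookup table maintained across splits.  Radii are scaled once, after
    all insertions.
    """
    tree = tree_base.copy()
    lut: dict[tuple, int] = {
        tuple(v.x_p) + tuple(v.x_d): v.id for v in tree.vessels.values()
    }
    for records in record_lists:
        for rec in records:
            key = rec.parent_key()
            if key not in lut:
                raise MergeError(
                    f"record {rec.sequence} of subdomain {rec.subdomain}: "
                    f"no live segment with endpoints {key}"
                )
            parent_id = lut.pop(key)
            parent = tree.vessels[parent_id]
            xp_old, xd_old = parent.x_p.copy(), parent.x_d.copy()
            stub_id, sib_id, term_id = add_terminal(
                tree, parent_id, rec.x_bif, rec.x_new,
                stage=f"merge-{rec.subdomain}"
            )
            lut[tuple(xp_old) + tuple(rec.x_bif)] = stub_id
            lut[tuple(rec.x_bif) + tuple(xd_old)] = sib_id
            lut[tuple(rec.x_bif) + tuple(rec.x_new)] = term_id
    assign_terminal_flows(tree)
    if rescale:
        model = viscosity_model if viscosity_model is not None else ConstantViscosity()
        fixed_point_viscosity_radii(tree, model)
    return tree


@dataclasses.dataclass
class PipelineResult:
    """All artifacts of a partitioned run."""

    base: VascularTree
    subtrees: list[VascularTree]
    records: list[list[InsertionRecord]]
    merged: VascularTree


def pdcco_pipeline(domain: PerfusionDomain, partition: DomainPartition,
                   baseline_stage: StageConfig,
                   subdomain_stages: list[StageConfig],
                   *, initial_tree: VascularTree | None = None,
                   inlet: dict | None = None,
                   seed: int = 0,
                   parallel: bool = False,
                   viscosity_model: ViscosityModel | None = None,
                   ) -> PipelineResult:
    """Baseline growth, per-subdomain concurrent growth, and merge.

    ``subdomain_stages`` holds one stage per subdomain (``stage.N`` terminals
    each).  Provide either ``initial_tree`` or ``inlet`` (a dict with keys
    ``x_p, x_d, r0, Q_in`` and optional ``gamma``).  With ``parallel=True``
    subdomains are grown by a thread pool; the result is identical to the
    serial path by construction.
    """
    if len(subdomain_stages) != partition.n_part:
        raise ValueError("need exactly one stage per subdomain")
    if initial_tree is None:
        if inlet is None:
            raise ValueError("provide initial_tree or inlet")
        initial_tree = VascularTree.from_root(
            inlet["x_p"], inlet["x_d"], r0=inlet["r0"], Q_in=inlet["Q_in"],
            gamma=inlet.get("gamma", 3.0),
        )
    base = grow(initial_tree, domain, baseline_stage,
                viscosity_model=viscosity_model)

    def _one(i: int):
        return grow_subdomain(base, partition, i, subdomain_stages[i], seed=seed)

    indices = range(partition.n_part)
    if parallel:
        with concurrent.futures.ThreadPoolExecutor() as pool:
            results = list(pool.map(_one, indices))
    else:
        results = [_one(i) for i in indices]
    subtrees = [t for t, _ in results]
    records = [r for _, r in results]
    merged = merge(base, records, viscosity_model=viscosity_model)
    log.info("pipeline: %d baseline + %s added -> %d terminals",
             base.n_terminals, [len(r) for r in records], merged.n_terminals)
    return PipelineResult(base=base, subtrees=subtrees, records=records,
                          merged=merged)
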