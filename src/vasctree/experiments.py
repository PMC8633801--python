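"""Desk-scale experiment harness.

Reduced-size versions of the bundled comparison studies: sensitivity of the
partitioned result to the baseline size, to the subdomain aspect ratio, a
multi-inlet cost-coefficient sweep, a scalability protocol, and a staged
renal-like demo.  All randomness flows from explicit seeds; each experiment
returns tidy tables and can write them as CSV.
"""

from __future__ import annotations

import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .dcco_growth import CostFunctional, StageConfig, grow
from .domain_geometry import BoxDomain, allometric_inlet_scaling, partition_axis_aligned
from .hemodynamics import DiameterViscosity, fixed_point_viscosity_radii, solve_pressures
from .morphometry import intravascular_volume, relative_volume_error
from .pdcco import grow_subdomain, merge, split_counts
from .vessel_tree import VascularTree

__all__ = [
    "box_setup",
    "four_inlet_tree",
    "grow_sequential",
    "grow_partitioned",
    "paired_volume_experiment",
    "sequential_cost_scaling",
    "experiment_harness",
]

log = logging.getLogger(__name__)

_EXPERIMENTS = ("baseline-sensitivity", "aspect-ratio", "multi-inlet-sweep",
                "scalability", "demo-kidney-like")


def box_setup(L: float = 1.0, Q_in: float = 0.002, r0: float = 0.075,
              seed: int | None = 0, allometric: bool = False,
              ) -> tuple[BoxDomain, dict]:
    """A 4L x 1 x 1 box with the inlet on the x = 0 face at (L/10) depth.

    With ``allometric=True`` the inlet data is rescaled from the L = 1
    reference volume (4 cm^3) by Q proportional to V and r0 to V^(3/8).
    """
    domain = BoxDomain([0, 0, 0], [4 * L, 1, 1], seed=seed)
    if allometric:
        Q_in, r0 = allometric_inlet_scaling(domain.volume, Q_in, r0, 4.0)
    inlet = {"x_p": np.array([0.0, 0.5, 0.5]),
             "x_d": np.array([L / 10.0, 0.5, 0.5]),
             "Q_in": Q_in, "r0": r0}
    return domain, inlet


def _root_tree(inlet: dict, gamma: float = 3.0) -> VascularTree:
    return VascularTree.from_root(inlet["x_p"], inlet["x_d"],
                                  r0=inlet["r0"], Q_in=inlet["Q_in"],
                                  gamma=gamma)


def four_inlet_tree(Q_in: float = 0.002, r0: float = 0.075,
                    gamma: float = 3.0) -> VascularTree:
    """Handcrafted external network supplying the side-2 cube centred at the
    origin through four inlet branches crossing the +x/-x faces (7 segments,
    4 terminals)."""
    from .vessel_tree import Vessel, assign_terminal_flows, rescale_radii

    tree = VascularTree(gamma=gamma, Q_in=Q_in, r0=r0)
    top = [0.0, 0.0, 2.5]
    edges = [
        # id, x_p, x_d, parent, children
        (0, [0, 0, 3.0], top, None, (1, 2)),
        (1, top, [1.4, 0, 1.4], 0, (3, 4)),
        (2, top, [-1.4, 0, 1.4], 0, (5, 6)),
        (3, [1.4, 0, 1.4], [0.5, 0.55, 0.2], 1, ()),
        (4, [1.4, 0, 1.4], [0.5, -0.55, 0.2], 1, ()),
        (5, [-1.4, 0, 1.4], [-0.5, 0.55, 0.2], 2, ()),
        (6, [-1.4, 0, 1.4], [-0.5, -0.55, 0.2], 2, ()),
    ]
    for vid, x_p, x_d, parent, children in edges:
        tree.vessels[vid] = Vessel(id=vid, x_p=x_p, x_d=x_d, r=r0,
                                   parent=parent, children=children)
    tree.root_id = 0
    tree._next_id = 7
    for vid, count in tree.recount_subtended().items():
        tree.vessels[vid].n_term_sub = count
    assign_terminal_flows(tree)
    rescale_radii(tree)
    return tree


def grow_sequential(tree: VascularTree, domain, n_total: int, seed,
                    f_n: float = 1.0, stage_kwargs: dict | None = None,
                    ) -> VascularTree:
    """Continue sequential growth until the tree has ``n_total`` terminals."""
    n_add = n_total - tree.n_terminals
    if n_add < 0:
        raise ValueError("tree already larger than n_total")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    stage = StageConfig(N=n_add, name="sequential", f_n=f_n, seed=0,
                        **(stage_kwargs or {}))
    return grow(tree, domain, stage, rng=rng)


def grow_partitioned(tree_base: VascularTree, domain, counts, n_add_total: int,
                     seed, f_n: float = 1.0,
                     stage_kwargs: dict | None = None) -> VascularTree:
    """Partition the domain, grow each subdomain from the shared baseline, and
    merge."""
    partition = partition_axis_aligned(domain, counts)
    n_each = split_counts(n_add_total, partition.n_part)
    records = []
    for i in range(partition.n_part):
        stage = StageConfig(N=n_each[i], name=f"sub{i}", f_n=f_n, seed=0,
                            **(stage_kwargs or {}))
        _, recs = grow_subdomain(tree_base, partition, i, stage, seed=seed)
        records.append(recs)
    return merge(tree_base, records)


def paired_volume_experiment(n_total: int = 500, n_base: int = 250,
                             counts=(4, 1, 1), n_instances: int = 3,
                             seed: int = 1, L: float = 1.0,
                             Q_in: float = 0.002, r0: float = 0.075,
                             f_n: float = 1.0,
                             with_pressure: bool = True) -> pd.DataFrame:
    """Matched-seed comparison of sequential vs partitioned generation.

    Per instance, one baseline tree with ``n_base`` terminals is grown and
    shared by both routes: the sequential route continues it to ``n_total``
    terminals, the partitioned route adds the same number of terminals split
    over the subdomains and merges.  Returns one row per instance with the
    intravascular volumes and (optionally) mean terminal pressure drops under
    the diameter-dependent viscosity law.
    """
    rows = []
    for k in range(n_instances):
        domain, inlet = box_setup(L=L, Q_in=Q_in, r0=r0, seed=seed + k)
        base = _root_tree(inlet)
        stage = StageConfig(N=n_base - 1, name="baseline", f_n=f_n,
                            seed=0)
        grow(base, domain, stage,
             rng=np.random.default_rng(np.random.SeedSequence((seed, k, 0))))
        seq = grow_sequential(base.copy(), domain, n_total,
                              seed=(seed, k, 1), f_n=f_n)
        par = grow_partitioned(base, domain, counts, n_total - n_base,
                               seed=seed * 1000 + k, f_n=f_n)
        row = {
            "instance": k,
            "n_base": n_base,
            "volume_sequential": intravascular_volume(seq),
            "volume_partitioned": intravascular_volume(par),
        }
        if with_pressure:
            model = DiameterViscosity()
            for name, t in (("sequential", seq), ("partitioned", par)):
                _, sol = fixed_point_viscosity_radii(t, model)
                row[f"drop_{name}"] = float(sol.terminal_drops(t).mean())
        rows.append(row)
        log.info("instance %d: V_seq=%.4g V_par=%.4g", k,
                 row["volume_sequential"], row["volume_partitioned"])
    return pd.DataFrame(rows)


def sequential_cost_scaling(ns=(250, 500, 1000, 2000), seed: int = 1,
                            f_n: float = 1.0) -> pd.DataFrame:
    """Wall time of sequential growth vs terminal count, with the fitted
    log-log slope attached as ``df.attrs['slope']``."""
    rows = []
    for n in ns:
        domain, inlet = box_setup(seed=seed)
        tree = _root_tree(inlet)
        t0 = time.perf_counter()
        grow(tree, domain, StageConfig(N=n - 1, name="timing", f_n=f_n,
                                       seed=seed))
        rows.append({"n_seq": n, "seconds": time.perf_counter() - t0})
    df = pd.DataFrame(rows)
    slope, _ = np.polyfit(np.log(df["n_seq"]), np.log(df["seconds"]), 1)
    df.attrs["slope"] = float(slope)
    return df


# ------------------------------------------------------------------ harness
def experiment_harness(name: str, overrides: dict | None = None,
                       out_dir=None) -> dict:
    """Run a named reduced-scale experiment; returns its tables and writes
    them as CSV when ``out_dir`` is given."""
    if name not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {_EXPERIMENTS}")
    o = dict(overrides or {})
    seed = int(o.pop("seed", 1))
    result: dict[str, pd.DataFrame] = {}

    if name == "baseline-sensitivity":
        n_total = int(o.pop("n_total", 400))
        n_instances = int(o.pop("n_instances", 3))
        frames = []
        for n_base in o.pop("n_bases", (100, 200)):
            df = paired_volume_experiment(
                n_total=n_total, n_base=int(n_base), n_instances=n_instances,
                seed=seed, with_pressure=False, **o)
            errors, summary = relative_volume_error(
                df["volume_partitioned"], df["volume_sequential"])
            df["relative_volume_error"] = errors
            frames.append(df)
        result["volumes"] = pd.concat(frames, ignore_index=True)

    elif name == "aspect-ratio":
        n_total = int(o.pop("n_total", 300))
        frames = []
        for L in o.pop("aspect_ratios", (0.5, 1.0, 2.0)):
            domain, inlet = box_setup(L=float(L), seed=seed, allometric=True)
            base = _root_tree(inlet)
            grow(base, domain, StageConfig(N=n_total // 2 - 1, seed=seed,
                                           name="baseline"))
            par = grow_partitioned(base, domain, (4, 1, 1),
                                   n_total - n_total // 2, seed=seed)
            frames.append(pd.DataFrame([{
                "aspect_ratio": L,
                "volume": intravascular_volume(par),
                "n_terminals": par.n_terminals,
            }]))
        result["volumes"] = pd.concat(frames, ignore_index=True)

    elif name == "multi-inlet-sweep":
        n_base = int(o.pop("n_base", 40))
        combos = o.pop("coefficients", ((1.0, 0.0, 0.0), (0.4, 0.3, 0.3),
                                        (0.0, 0.5, 0.5)))
        rows = []
        for c_v, c_p, c_d in combos:
            tree = four_inlet_tree()
            cube = BoxDomain([-1, -1, -1], [1, 1, 1], seed=seed)
            cost = (CostFunctional.volumetric() if (c_v, c_p, c_d) == (1.0, 0.0, 0.0)
                    else CostFunctional.sprouting(c_v, c_p, c_d, V_ref=8.0,
                                                  l_ref=2.0, r_ref=0.075))
            grow(tree, cube, StageConfig(N=n_base - tree.n_terminals,
                                         cost=cost, seed=seed, name="baseline"))
            # flow fraction carried by each of the four inlet branches
            inlets = sorted(
                (v for v in tree.vessels.values()
                 if abs(v.x_p[0]) > 1.0 and abs(v.x_d[0]) < 1.0),
                key=lambda v: (v.x_p[0], v.x_d[1]),
            )
            fractions = [v.Q / tree.Q_in for v in inlets]
            rows.append({"c_v": c_v, "c_p": c_p, "c_d": c_d,
                         "flow_fractions": fractions,
                         "flow_std": float(np.std(fractions))})
        result["sweep"] = pd.DataFrame(rows)

    elif name == "scalability":
        n_total = int(o.pop("n_total", 2000))
        counts = tuple(o.pop("counts", (4, 4, 1)))
        domain = BoxDomain([0, 0, 0], [5, 5, 2.3], seed=seed)
        inlet = {"x_p": np.array([0.0, 2.5, 1.15]),
                 "x_d": np.array([0.5, 2.5, 1.15]),
                 "Q_in": 0.002, "r0": 0.075}
        base = _root_tree(inlet)
        n_base = int(o.pop("n_base", max(200, n_total // 20)))
        t0 = time.perf_counter()
        grow(base, domain, StageConfig(N=n_base - 1, seed=seed, name="baseline"))
        t_base = time.perf_counter() - t0
        t0 = time.perf_counter()
        merged = grow_partitioned(base, domain, counts, n_total - n_base,
                                  seed=seed, f_n=float(o.pop("f_n", 0.5)))
        t_par = time.perf_counter() - t0
        sol = solve_pressures(merged)
        result["summary"] = pd.DataFrame([{
            "n_part": int(np.prod(counts)),
            "n_terminals": merged.n_terminals,
            "n_segments": merged.n_segments,
            "baseline_seconds": t_base,
            "partitioned_seconds": t_par,
            "volume": intravascular_volume(merged),
            "mean_terminal_drop_mmHg": float(sol.terminal_drops(merged).mean()),
        }])

    elif name == "demo-kidney-like":
        from .presets import renal_sprouting_cost

        n_total = int(o.pop("n_total", 300))
        domain = BoxDomain([0, 0, 0], [4, 2, 1.5], seed=seed)
        core = BoxDomain([1.2, 0.6, 0.4], [2.8, 1.4, 1.1], seed=seed)
        inlet = {"x_p": np.array([0.0, 1.0, 0.75]),
                 "x_d": np.array([0.35, 1.0, 0.75]),
                 "Q_in": 0.01, "r0": 0.1}
        tree = _root_tree(inlet)
        grow(tree, domain, StageConfig(N=20, cost=renal_sprouting_cost(),
                                       name="S1", f_n=2.0, n_bif=21,
                                       seed=seed), sample_domain=core)
        grow(tree, domain, StageConfig(N=n_total // 2, name="S2", f_n=1.0,
                                       seed=seed + 1))
        merged = grow_partitioned(tree, domain, (2, 2, 1),
                                  n_total - tree.n_terminals, seed=seed)
        result["summary"] = pd.DataFrame([{
            "n_terminals": merged.n_terminals,
            "volume": intravascular_volume(merged),
        }])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, df in result.items():
            df.to_csv(out_dir / f"{name}-{key}.csv", index=False)
    return result
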