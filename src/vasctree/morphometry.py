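"""Morphometric and functional statistics of vessel networks.

Generation-wise profiles (radius, length, aspect ratio, pressure), Strahler
ordering with connectivity matrix and per-order summaries, intravascular and
subtended volumes, radius-length histograms, and the relative-volume
agreement metric between independently generated network ensembles.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .hemodynamics import FlowSolution
from .vessel_tree import VascularTree, generation_of

__all__ = [
    "intravascular_volume",
    "relative_volume_error",
    "strahler_orders",
    "connectivity_matrix",
    "subtended_volumes",
    "generation_table",
    "box_summary",
    "generation_profiles",
    "radius_length_histogram",
    "strahler_summary",
    "profiles",
]


def intravascular_volume(tree: VascularTree) -> float:
    """Total lumen volume, sum of pi * l * r^2 over all segments (cm^3)."""
    return math.fsum(math.pi * v.length * v.r ** 2 for v in tree.vessels.values())


def relative_volume_error(pdcco_volumes, dcco_volumes):
    """Signed per-instance volume discrepancies against the sequential mean.

    ``e_k = (V_parallel,k - mean(V_sequential)) / mean(V_sequential)``.
    Returns ``(errors, summary)`` where summary holds median/mean statistics
    of the signed errors and of their absolute values.
    """
    dcco_volumes = np.asarray(list(dcco_volumes), dtype=float)
    if dcco_volumes.size == 0:
        raise ValueError("sequential volume list is empty")
    ref = float(dcco_volumes.mean())
    if ref == 0:
        raise ValueError("mean sequential volume is zero")
    errors = (np.asarray(list(pdcco_volumes), dtype=float) - ref) / ref
    summary = {
        "median": float(np.median(errors)),
        "mean": float(np.mean(errors)),
        "median_abs": float(np.median(np.abs(errors))),
        "mean_abs": float(np.mean(np.abs(errors))),
        "reference_volume": ref,
    }
    return errors, summary


def strahler_orders(tree: VascularTree) -> dict[int, int]:
    """Leaf-up ordering: terminals are 0; a parent of equal-order daughters is
    promoted by one, otherwise it takes the larger order."""
    orders: dict[int, int] = {}
    for v in tree.post_order():
        if v.is_terminal:
            orders[v.id] = 0
        else:
            a, b = (orders[c] for c in v.children)
            orders[v.id] = a + 1 if a == b else max(a, b)
    return orders


def connectivity_matrix(tree: VascularTree,
                        orders: dict[int, int] | None = None) -> np.ndarray:
    """Counts of parent-child pairs by (parent order, child order)."""
    orders = orders if orders is not None else strahler_orders(tree)
    size = max(orders.values()) + 1
    mat = np.zeros((size, size), dtype=np.int64)
    for v in tree.vessels.values():
        for c in v.children:
            mat[orders[v.id], orders[c]] += 1
    return mat


def subtended_volumes(tree: VascularTree) -> dict[int, float]:
    """Intravascular volume of the subtree hanging from each vessel (cm^3)."""
    out: dict[int, float] = {}
    for v in tree.post_order():
        own = math.pi * v.length * v.r ** 2
        out[v.id] = own + sum(out[c] for c in v.children)
    return out


def generation_table(tree: VascularTree,
                     flow: FlowSolution | None = None) -> pd.DataFrame:
    """Tidy per-vessel table: generation, radius, length, aspect ratio and
    (when a flow solution is given) distal pressure relative to the inlet and
    its magnitude as a drop."""
    rows = []
    for v in tree.pre_order():
        row = {
            "id": v.id,
            "generation": generation_of(tree, v.id),
            "radius": v.r,
            "length": v.length,
            "aspect_ratio": v.length / (2.0 * v.r),
            "flow": v.Q,
            "terminal": v.is_terminal,
        }
        if flow is not None:
            row["pressure_proximal"] = flow.p_prox[v.id]
            row["pressure"] = flow.p_dist[v.id]
            row["pressure_drop"] = flow.drop(v.id)
        rows.append(row)
    return pd.DataFrame(rows)


def box_summary(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles and 1.5*IQR whiskers clipped to the data range."""
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(lo), "whisker_high": float(hi),
            "count": int(values.size)}


def generation_profiles(tree: VascularTree,
                        flow: FlowSolution | None = None,
                        quantities: tuple[str, ...] = (
                            "radius", "length", "aspect_ratio", "pressure_drop"),
                        ) -> pd.DataFrame:
    """Box-plot summaries of each quantity per generation (contiguous from 0)."""
    table = generation_table(tree, flow)
    rows = []
    for gen, grp in table.groupby("generation"):
        for q in quantities:
            if q not in grp.columns:
                continue
            rows.append({"generation": int(gen), "quantity": q,
                         **box_summary(grp[q].to_numpy())})
    return pd.DataFrame(rows)


def radius_length_histogram(tree: VascularTree, bins: int = 30) -> pd.DataFrame:
    """Joint histogram of segments over (radius, length); mass sums to the
    segment count."""
    radii = np.array([v.r for v in tree.vessels.values()])
    lengths = np.array([v.length for v in tree.vessels.values()])
    h, r_edges, l_edges = np.histogram2d(radii, lengths, bins=bins)
    r_idx, l_idx = np.nonzero(h)
    return pd.DataFrame({
        "radius_low": r_edges[r_idx], "radius_high": r_edges[r_idx + 1],
        "length_low": l_edges[l_idx], "length_high": l_edges[l_idx + 1],
        "count": h[r_idx, l_idx].astype(int),
    })


def strahler_summary(tree: VascularTree,
                     flow: FlowSolution | None = None) -> pd.DataFrame:
    """Per-order vessel count, combined lumen area, mean flow and pressure."""
    orders = strahler_orders(tree)
    rows = []
    by_order: dict[int, list[int]] = {}
    for vid, o in orders.items():
        by_order.setdefault(o, []).append(vid)
    for o in sorted(by_order):
        vids = by_order[o]
        area = math.fsum(math.pi * tree.vessels[v].r ** 2 for v in vids)
        row = {"order": o, "count": len(vids), "lumen_area": area,
               "mean_radius": float(np.mean([tree.vessels[v].r for v in vids])),
               "mean_flow": float(np.mean([tree.vessels[v].Q for v in vids]))}
        if flow is not None:
            row["mean_pressure_drop"] = float(
                np.mean([flow.drop(v) for v in vids])
            )
        rows.append(row)
    return pd.DataFrame(rows)


def profiles(tree: VascularTree,
             flow: FlowSolution | None = None) -> dict[str, pd.DataFrame]:
    """All standard characterizations bundled as tidy tables."""
    orders = strahler_orders(tree)
    sub = subtended_volumes(tree)
    scatter = pd.DataFrame({
        "radius": [tree.vessels[v].r for v in sorted(sub)],
        "subtended_volume": [sub[v] for v in sorted(sub)],
        "strahler": [orders[v] for v in sorted(sub)],
    })
    return {
        "generation_profiles": generation_profiles(tree, flow),
        "radius_length": radius_length_histogram(tree),
        "strahler": strahler_summary(tree, flow),
        "connectivity": pd.DataFrame(connectivity_matrix(tree, orders)),
        "subtended": scatter,
    }
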