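"""Poiseuille network haemodynamics with diameter-dependent blood viscosity.

Internally everything is CGS (cm, s, poise, dyn/cm^2); reported pressures are
mmHg relative to a null reference at the inlet.  The diameter-dependent
viscosity is the in-vitro relative-viscosity law of Pries et al. scaled by the
plasma viscosity, giving the apparent viscosity reduction in narrow tubes.
The viscosity depends on the diameters being solved for, so the coupled
problem is linearized by plain fixed-point iteration between viscosity
updates and radius rescaling.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .vessel_tree import VascularTree, rescale_radii

__all__ = [
    "ViscosityModel",
    "ConstantViscosity",
    "DiameterViscosity",
    "viscosity",
    "segment_resistance",
    "FlowSolution",
    "solve_pressures",
    "fixed_point_viscosity_radii",
    "ConvergenceError",
    "MMHG_PER_DYN_CM2",
]

#: 1 dyn/cm^2 in mmHg
MMHG_PER_DYN_CM2 = 7.50062e-4


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(f"{message} (residual history: {history})")
        self.history = history


class ViscosityModel:
    """Maps a lumen diameter (um) to an effective viscosity (cP)."""

    kind = "abstract"

    def __call__(self, d_um: float) -> float:
        raise NotImplementedError


@dataclasses.dataclass(frozen=True)
class ConstantViscosity(ViscosityModel):
    value_cp: float = 3.6
    kind: str = dataclasses.field(default="constant", init=False)

    def __call__(self, d_um: float) -> float:
        if d_um <= 0:
            raise ValueError("diameter must be positive")
        return self.value_cp


@dataclasses.dataclass(frozen=True)
class DiameterViscosity(ViscosityModel):
    """In-vitro relative viscosity times plasma viscosity.

    ``mu(d) = mu_plasma * [1 + (mu45 - 1) * ((1-H)^C - 1)/((1-0.45)^C - 1)]``
    with ``mu45 = 220 exp(-1.3 d) + 3.2 - 2.44 exp(-0.06 d^0.645)`` and the
    shape exponent ``C`` of the same parameterization (d in um).
    """

    plasma_cp: float = 1.2
    hematocrit: float = 0.45
    kind: str = dataclasses.field(default="diameter", init=False)

    def relative(self, d_um: float) -> float:
        if d_um <= 0:
            raise ValueError("diameter must be positive")
        d = float(d_um)
        mu45 = 220.0 * math.exp(-1.3 * d) + 3.2 - 2.44 * math.exp(-0.06 * d ** 0.645)
        if abs(self.hematocrit - 0.45) < 1e-15:
            return mu45
        dampen = 1.0 / (1.0 + 1e-11 * d ** 12)
        c = (0.8 + math.exp(-0.075 * d)) * (-1.0 + dampen) + dampen
        h = self.hematocrit
        return 1.0 + (mu45 - 1.0) * ((1.0 - h) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0)

    def __call__(self, d_um: float) -> float:
        return self.plasma_cp * self.relative(d_um)


def viscosity(d_um: float, model: ViscosityModel) -> float:
    """Effective viscosity (cP) of a vessel with lumen diameter ``d_um`` (um)."""
    return model(d_um)


def segment_resistance(l: float, r: float, mu: float) -> float:
    """Poiseuille resistance of one segment, mmHg*s/cm^3.

    ``l`` and ``r`` in cm, ``mu`` in poise; ``R = 8 mu l / (pi r^4)`` in
    dyn*s/cm^5 converted to mmHg*s/cm^3.
    """
    if l <= 0 or r <= 0 or mu <= 0:
        raise ValueError("length, radius and viscosity must be positive")
    return 8.0 * mu * l / (math.pi * r ** 4) * MMHG_PER_DYN_CM2


@dataclasses.dataclass
class FlowSolution:
    """Pressures (mmHg, inlet = 0) and resistances for every vessel."""

    p_prox: dict[int, float]
    p_dist: dict[int, float]
    resistance: dict[int, float]
    iterations: int = 1
    residual: float = 0.0

    def drop(self, vessel_id: int) -> float:
        """Magnitude of the pressure drop from the inlet to the distal end."""
        return -self.p_dist[vessel_id]

    def terminal_drops(self, tree: VascularTree) -> np.ndarray:
        return np.array([self.drop(t) for t in sorted(tree.terminal_ids())])


def solve_pressures(tree: VascularTree, iterations: int = 1,
                    residual: float = 0.0) -> FlowSolution:
    """March pressures from the inlet: ``p_dist = p_prox - Q R`` per segment."""
    p_prox: dict[int, float] = {}
    p_dist: dict[int, float] = {}
    res: dict[int, float] = {}
    for v in tree.pre_order():
        if v.parent is None:
            p_prox[v.id] = 0.0
        else:
            if v.parent not in p_dist:
                raise ValueError(f"vessel {v.id} disconnected from solved network")
            p_prox[v.id] = p_dist[v.parent]
        res[v.id] = segment_resistance(v.length, v.r, v.mu)
        p_dist[v.id] = p_prox[v.id] - v.Q * res[v.id]
    return FlowSolution(p_prox, p_dist, res, iterations, residual)


def update_viscosities(tree: VascularTree, model: ViscosityModel) -> None:
    """Set each vessel's effective viscosity from its current diameter."""
    for v in tree.vessels.values():
        v.mu = model(2.0e4 * v.r) / 100.0  # cm diameter -> um, cP -> poise


def fixed_point_viscosity_radii(
    tree: VascularTree,
    model: ViscosityModel,
    tol: float = 1e-6,
    max_iter: int = 100,
    relax: float | None = None,
) -> tuple[VascularTree, FlowSolution]:
    """Self-consistent radii and viscosities by plain fixed-point iteration.

    Each iteration updates viscosities from the current diameters and rescales
    the radii; convergence is declared when the largest relative radius change
    within an iteration falls below ``tol``.  A constant-viscosity model
    converges in exactly one iteration.  ``relax`` optionally damps the radius
    update (``r <- (1-relax) r_old + relax r_new``).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    update_viscosities(tree, model)
    rescale_radii(tree)  # consistent starting point, not counted
    history: list[float] = []
    for it in range(1, max_iter + 1):
        before = {vid: v.r for vid, v in tree.vessels.items()}
        update_viscosities(tree, model)
        rescale_radii(tree)
        if relax is not None:
            for vid, v in tree.vessels.items():
                v.r = (1.0 - relax) * before[vid] + relax * v.r
        residual = max(
            abs(v.r - before[vid]) / before[vid] for vid, v in tree.vessels.items()
        )
        history.append(residual)
        if not math.isfinite(residual):
            raise ConvergenceError("non-finite radii during fixed point", history)
        if residual < tol:
            return tree, solve_pressures(tree, iterations=it, residual=residual)
    raise ConvergenceError(
        f"viscosity/radius fixed point did not converge in {max_iter} iterations",
        history,
    )
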