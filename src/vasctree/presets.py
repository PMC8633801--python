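"""Built-in experiment presets: anatomical inputs and staged parameter tables.

These constants parameterize the bundled demonstration experiments (box
scalability setup, renal-demo staged scheme).  They are inputs, not results:
every derived number in the acceptance report is recomputed from them at run
time.
"""

from __future__ import annotations

from .dcco_growth import CostFunctional, StageConfig

# ----------------------------------------------------------- renal demo model
#: anatomical model volumes (cm^3) and dimensions (cm) of the renal demo
RENAL_MODEL = {
    "dimensions_cm": (11.7, 6.54, 4.92),
    "total_volume_cm3": 155.32,
    "cortical_volume_cm3": 74.65,
    "medullary_volume_cm3": 80.65,
    "n_pyramids": 13,
}

#: inlet boundary data of the renal demo
RENAL_INLET = {"Q_in": 14.0, "r0": 0.27}

#: baseline terminal count before partitioned growth
RENAL_N_BASE = 5000

#: terminals added per subdomain in the partitioned phase (8 transverse slabs)
RENAL_SUBDOMAIN_ADDITIONS = [7742, 13870, 11809, 11942, 13803, 12958, 14668, 8208]


def cortical_medullary_ratio(model: dict | None = None) -> float:
    """Cortical/medullary volume ratio implied by the model volumes."""
    model = model or RENAL_MODEL
    return model["cortical_volume_cm3"] / model["medullary_volume_cm3"]


def renal_sprouting_cost() -> CostFunctional:
    """Sprouting functional of the renal demo's first stage."""
    return CostFunctional.sprouting(c_v=0.999, c_p=0.0, c_d=0.001,
                                    V_ref=100.0, l_ref=1.0, r_ref=1.0,
                                    gamma=3.0)


def renal_stage_table(n_subdomain: int, delta_1: float = 0.0,
                      seed: int = 0) -> list[StageConfig]:
    """Staged parameter scheme of the renal demo for one subdomain's
    additions ``n_subdomain``: four volumetric stages with progressively
    shrinking neighbourhood factors.  Cumulative terminal targets are Q, 2Q,
    3Q and 4Q + R with (Q, R) = divmod(n_subdomain, 4), i.e. equal increments
    with the remainder in the last stage."""
    q, r = divmod(int(n_subdomain), 4)
    counts = [q, q, q, q + r]
    f_ns = [1.0, 0.5, 0.25, 0.125]
    return [
        StageConfig(N=counts[i], name=f"S{i + 4}", f_n=f_ns[i], n_bif=7,
                    f_r=0.9, theta_min=30.0, phi_min=0.0, delta=delta_1,
                    seed=seed + i)
        for i in range(4)
    ]


# -------------------------------------------------------- scalability setup
#: parallelepipedal scalability domain (cm) and inlet data
SCALABILITY_BOX = ((0.0, 0.0, 0.0), (5.0, 5.0, 2.3))
SCALABILITY_INLET = {"Q_in": 0.002, "r0": 0.075}  # 2 mm^3/s in cm^3/s
SCALABILITY_PARTITIONS = [(4, 4, 1), (5, 5, 1), (6, 6, 1)]  # 16, 25, 36 cells
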