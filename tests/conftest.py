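import numpy as np
import pytest

from vasctree.vessel_tree import VascularTree, add_terminal, assign_terminal_flows, rescale_radii


def build_random_tree(n_terminals: int, rng: np.random.Generator,
                      r0: float = 0.05, Q_in: float = 1.0,
                      gamma: float = 3.0) -> VascularTree:
    """Random strict binary tree grown by repeated splits inside the unit box
    (pure object-model construction, no optimization)."""
    tree = VascularTree.from_root([0.0, 0.5, 0.5], [0.2, 0.5, 0.5],
                                  r0=r0, Q_in=Q_in, gamma=gamma)
    while tree.n_terminals < n_terminals:
        vid = int(rng.choice(list(tree.vessels)))
        v = tree.vessels[vid]
        t = rng.uniform(0.25, 0.75)
        x_bif = v.x_p + t * (v.x_d - v.x_p)
        x_new = rng.uniform(0.05, 0.95, size=3)
        if np.linalg.norm(x_new - x_bif) < 1e-3:
            continue
        add_terminal(tree, vid, x_bif, x_new)
    assign_terminal_flows(tree)
    rescale_radii(tree)
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree(rng):
    return build_random_tree(8, rng)


@pytest.fixture
def medium_tree(rng):
    return build_random_tree(32, rng)
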