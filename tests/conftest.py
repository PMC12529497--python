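import numpy as np
import pytest

from mechanopheno import synthgen


@pytest.fixture(scope="session")
def traction_scene():
    """Default contractile-patch bead scene (256^2, 30 kPa gel)."""
    spec = synthgen.SyntheticTractionSpec(seed=3)
    ref, dfm, traction, disp, gt = synthgen.gen_traction_scene(spec)
    return {"spec": spec if spec.patches else spec.default_cell_patch(),
            "ref": ref, "dfm": dfm, "traction": traction, "disp": disp,
            "gt": gt}


@pytest.fixture(scope="session")
def prw_ensemble():
    """300 persistent random walks at the default acquisition settings."""
    spec = synthgen.SyntheticPRWSpec(n_cells=300, seed=2)
    trajs, gt = synthgen.gen_prw_trajectories(spec)
    return {"spec": spec, "trajs": trajs, "gt": gt}


@pytest.fixture(scope="session")
def fa_scene():
    spec = synthgen.SyntheticFASceneSpec(seed=3)
    fa_img, nuc_img, cell_img, gt = synthgen.gen_fa_scene(spec)
    return {"spec": spec, "fa": fa_img, "nuclei": nuc_img,
            "cell": cell_img, "truth": gt.params["fa_table"], "gt": gt}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
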