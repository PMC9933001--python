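import numpy as np
import pytest

from bundlerepro import BundleSpec, RunConfig, run_study, simulate_study
from bundlerepro.synthetic import small_confound_plan


def small_pathways(n_streamlines: int = 300) -> dict:
    return {
        "ARC": BundleSpec(kind="arc", radius=30.0, angle_deg=180.0, n_streamlines=n_streamlines),
        "STRAIGHT": BundleSpec(
            kind="straight", length=60.0, origin=(0.0, -20.0, 10.0), n_streamlines=n_streamlines
        ),
    }


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory):
    """The packaged synthetic study: 2 subjects x 3 confounds x 2 pathways."""
    out = tmp_path_factory.mktemp("study")
    simulate_study(
        str(out),
        n_subjects=2,
        pathways=small_pathways(),
        plan=small_confound_plan(),
        seed=11,
        with_dwi=True,
    )
    return out


@pytest.fixture(scope="session")
def small_study_results(small_study_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("results")
    cfg = RunConfig(manifest=str(small_study_dir / "manifest.yaml"), out_dir=str(out), seed=11)
    return run_study(cfg), out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
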