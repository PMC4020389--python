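import numpy as np
import pytest

from tonguelab import synth
from tonguelab.config import CheckerPatchConfig, CorrectionConfig, PipelineConfig


def make_phantom_config(phantom) -> PipelineConfig:
    """Pipeline config whose checker layout matches a rendered phantom."""
    patches = [
        CheckerPatchConfig(
            patch_id=f"P{i + 1:02d}", role=role, rectangle=region, reference=ref
        )
        for i, (role, region, ref) in enumerate(
            zip(phantom.checker_roles, phantom.checker_regions, phantom.checker_references)
        )
    ]
    return PipelineConfig(correction=CorrectionConfig(patches=patches))


@pytest.fixture(scope="session")
def default_phantom():
    return synth.generate_tongue_image(synth.TonguePhantomSpec(seed=5))


@pytest.fixture(scope="session")
def phantom_config(default_phantom):
    return make_phantom_config(default_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
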