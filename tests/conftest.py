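import numpy as np
import pytest

from alismoke import (
    CiliaRegion,
    CiliaVideoSpec,
    TwoCohortExpressionSpec,
    generate_cilia_video,
    generate_two_cohort_expression,
)


def region_mask(h, w, y0, y1, x0, x1):
    mask = np.zeros((h, w), dtype=bool)
    mask[y0:y1, x0:x1] = True
    return mask


@pytest.fixture(scope="session")
def clean_8hz_video():
    """Noiseless 20x20 region beating at 8 Hz, 30 fps, 512 frames."""
    spec = CiliaVideoSpec(
        height=40,
        width=40,
        n_frames=512,
        fps=30.0,
        regions=(CiliaRegion(region_mask(40, 40, 5, 25, 5, 25), 8.0, 10.0, 0.0),),
        noise_sd=0.0,
        seed=11,
    )
    return generate_cilia_video(spec)


@pytest.fixture(scope="session")
def concordant_cohorts():
    """Two-cohort expression with fully concordant signature, large-n in vitro."""
    spec = TwoCohortExpressionSpec(
        invitro_donors=10, discordant_fraction=0.0, seed=21
    )
    return generate_two_cohort_expression(spec)


@pytest.fixture(scope="session")
def discordant_cohorts():
    """Two-cohort expression with 14% of signature directions flipped in vivo."""
    spec = TwoCohortExpressionSpec(
        invitro_donors=10, discordant_fraction=0.14, seed=22
    )
    return generate_two_cohort_expression(spec)
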