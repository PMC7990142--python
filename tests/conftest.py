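import warnings

import numpy as np
import pytest

import agetraj as at

# statsmodels emits convergence chatter on tiny fixtures; the fits record
# their own convergence state, which the tests assert on directly
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def bone_spec():
    """Percent-bone-volume-like trait: control decline 1.941 %/100 d with
    plausible between/within-mouse spread."""
    return at.GenerativeTraitSpec(
        "BV.TV", beta0=55.0, beta1_sex=2.0, beta3_slope=-1.941,
        sd_intercept=3.0, sd_slope=0.5, sd_residual=1.5,
    )


@pytest.fixture
def quarterly_design():
    """Single-arm quarterly design, 19 -> 30 months, no replacements."""
    return at.StudyDesignSpec(
        n_per_sex_per_arm=20, treatments=("control",),
        max_age_days=578.0 + 3 * 91.0 + 1.0, rolling_recruitment=False,
    )
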