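import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import twinlag as tl
from twinlag import calibration as cal
from twinlag.riclpm import derived_stability, fit_riclpm

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

#: 3,000 pairs at the study's MZ:DZ composition (577:961)
N_MZ_3000, N_DZ_3000 = 1126, 1874


@pytest.fixture(scope="session")
def study_params():
    """Generating RI-CLPM parameters at the study-calibrated conditions."""
    return cal.study_riclpm_params()


@pytest.fixture(scope="session")
def recovery_study(study_params):
    """One simulate → residualize → fit cycle at 3,000 pairs, shared by
    the recovery-oriented tests (the fit is the expensive part)."""
    panel = tl.simulate_riclpm_panel(study_params, N_MZ_3000, N_DZ_3000, seed=7)
    resid = tl.residualize_on_sex(panel)
    fit = fit_riclpm(resid, seed=0)
    return {
        "params": study_params,
        "panel": panel,
        "resid": resid,
        "fit": fit,
        "derived": derived_stability(fit),
    }


@pytest.fixture(scope="session")
def composite_cholesky_fit():
    """Bivariate AE Cholesky simulate → fit cycle on composite phenotypes."""
    params = cal.study_cholesky_params()
    panel = tl.simulate_cholesky_panel(params, N_MZ_3000, N_DZ_3000, seed=5)
    variables = [(lab, 1) for lab in params.labels]
    fit = tl.fit_cholesky(panel, variables, model="AE", seed=0)
    return {"params": params, "panel": panel, "fit": fit,
            "components": tl.variance_components(fit)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20250930)
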