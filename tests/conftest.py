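import numpy as np
import pytest

from bsikinetics import (
    Biomarker,
    MicrobialGroup,
    SimulationScenario,
    TrueKinetics,
    WINDOW,
)

CRP_KIN = TrueKinetics(c_true=-3.1, level_at_c=70.0, slope_pre=-1.5,
                       slope_post=36.3)
PA_KIN = TrueKinetics(c_true=-1.3, level_at_c=33.0, slope_pre=0.1,
                      slope_post=-1.8)


def full_profile(p: float = 1.0) -> dict[int, float]:
    return {d: p for d in range(WINDOW[0], WINDOW[1] + 1)}


def make_scenario(
    n_patients: int = 20,
    crp_kin: TrueKinetics = CRP_KIN,
    pa_kin: TrueKinetics = PA_KIN,
    crp_noise_sd_log: float = 0.0,
    pa_noise_sd: float = 0.0,
    sampling_p: float = 1.0,
    group_probs: dict | None = None,
    per_group_kinetics: dict | None = None,
    seed: int = 0,
) -> SimulationScenario:
    """Compact scenario builder for tests (defaults: zero noise, full sampling)."""
    group_probs = group_probs or {
        MicrobialGroup.GRAM_POS: 0.5,
        MicrobialGroup.GRAM_NEG: 0.5,
    }
    if per_group_kinetics is None:
        per = {Biomarker.CRP: crp_kin, Biomarker.PA: pa_kin}
        per_group_kinetics = {g: per for g in group_probs}
    return SimulationScenario(
        n_patients=n_patients,
        group_probs=group_probs,
        kinetics=per_group_kinetics,
        sampling_profile=full_profile(sampling_p),
        crp_noise_sd_log=crp_noise_sd_log,
        pa_noise_sd=pa_noise_sd,
        seed=seed,
    )


@pytest.fixture
def zero_noise_cohort():
    from bsikinetics import generate_cohort

    return generate_cohort(make_scenario(n_patients=12, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
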