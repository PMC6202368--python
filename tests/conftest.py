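import numpy as np
import pytest

from memskin import (
    Recording,
    SkinCircuitParams,
    StratumCorneumParams,
    SweatDuctParams,
    VoltageStimulus,
    generate_waveform,
)

# canonical noiseless parameter sets used across the suite


@pytest.fixture(scope="session")
def duct_only_params() -> SkinCircuitParams:
    """A sweat-duct memristor with the stratum-corneum branch switched off."""
    return SkinCircuitParams(
        duct=SweatDuctParams(g_min=8e-6, g_max=45e-6, x0=0.5,
                             a_plus=0.12, a_minus=0.12, tau_x=8.0),
        sc=StratumCorneumParams(g_ref=0.0, b_ntc=0.0, c_s=0.0),
        e_dc=0.0, noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def thermistor_params() -> SkinCircuitParams:
    """Stratum-corneum NTC thermistor + capacitance, no duct contact."""
    return SkinCircuitParams(
        duct=SweatDuctParams(g_min=0.0, g_max=0.0, x0=0.0,
                             a_plus=0.0, a_minus=0.0, tau_x=1.0),
        sc=StratumCorneumParams(g_ref=3e-6, b_ntc=6000.0, t_ref=306.0, t_amb=306.0,
                                c_th=2.2e-6, r_th=6e5, c_s=15.6e-9),
        e_dc=0.0, noise_sd=0.0,
    )


def make_sine_recording(i_of_t, amplitude=1.0, frequency=1.0, periods=1,
                        samples_per_period=500, sign=1) -> Recording:
    """Build a recording with an analytically prescribed current."""
    stim = VoltageStimulus("sinusoidal", amplitude, frequency,
                           periods=periods, samples_per_period=samples_per_period,
                           sign=sign)
    t, v = generate_waveform(stim)
    return Recording("analytic", "forehead", stim, t, v, np.asarray(i_of_t(t), dtype=float))
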