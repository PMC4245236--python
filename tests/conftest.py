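import logging

import pytest

from msdeconv.pipeline import deconvolve
from msdeconv.simulate import NoiseModel, build_preset, simulate_eics, simulate_peak_table

logging.getLogger("msdeconv").setLevel(logging.ERROR)
logging.getLogger("msdeconv.pipeline").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def glutamate_run():
    """Noiseless glutamate scenario: (peaks, truth, cfg, result)."""
    compounds, cfg = build_preset("glutamate")
    peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=7))
    result = deconvolve(peaks, cfg)
    return peaks, truth, cfg, result


@pytest.fixture(scope="session")
def glutamate_eic_run():
    """Glutamate scenario with EIC traces attached before deconvolution."""
    compounds, cfg = build_preset("glutamate")
    peaks, truth = simulate_peak_table(
        compounds, NoiseModel(seed=7, n_contaminant_peaks=3)
    )
    simulate_eics(peaks, truth, compounds)
    result = deconvolve(peaks, cfg)
    return peaks, truth, cfg, result


@pytest.fixture()
def dipeptide_run():
    compounds, cfg = build_preset("glu_met_dipeptide")
    peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=3))
    result = deconvolve(peaks, cfg)
    return peaks, truth, cfg, result
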