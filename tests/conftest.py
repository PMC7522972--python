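"""Shared fixtures: expensive pipeline runs are computed once per session.

All inputs are generated programmatically; nothing is loaded from disk.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from t1t2map import (
    AcquisitionScheme,
    LogGrid2D,
    classify_peaks_rst,
    detect_peaks,
    featurize,
    generate_cohort,
    invert,
    preset_phenotype,
    simulate_decay,
)
from t1t2map.cli_io import binary_disease_labels

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

# published reservoir coordinates (T1 ms, T2 ms, printed A-ratio)
TABLE_ROWS = {
    "oxygenated": {"R": (562, 141, 3.99), "S": (335, 4.47, 74.94),
                   "T": (188, 1.12, 167.86)},
    "oxidized": {"R": (217, 120, 1.81), "S": (120, 4.18, 28.71),
                 "Ti": (50.3, 1.34, 37.54), "T0": (2.43, 0.78, 3.12)},
    "deoxygenated": {"R": (463, 102, 4.53), "S": (242, 2.71, 89.30),
                     "T": (175, 0.565, 309.73)},
    "wild_type": {"R": (562, 141, 3.99), "S": (335, 4.47, 74.94),
                  "T": (188, 1.12, 167.9)},
    "hbe": {"R": (631, 158, 3.99), "S": (335, 4.22, 79.39),
            "T": (106, 1.06, 100.0)},
    "hbd": {"R": (640, 165, 3.88), "S": (373, 4.18, 89.23)},
    "rare_beta_thal": {"R": (640, 165, 3.88), "S": (362, 6.48, 55.86),
                       "T": (172, 1.40, 122.9)},
}


def cell_error(recovered_ms: float, true_ms: float, cell_decades: float,
               ) -> float:
    """Distance between recovered and true coordinate in grid cells."""
    return abs(np.log10(recovered_ms / true_ms)) / cell_decades


@pytest.fixture(scope="session")
def default_grid() -> LogGrid2D:
    return LogGrid2D()


@pytest.fixture(scope="session")
def oxygenated_spectrum():
    """Noiseless oxygenated inversion at the standard acquisition."""
    data = simulate_decay(preset_phenotype("oxygenated"),
                          AcquisitionScheme(n_echoes=4000, noise_sd=0.0))
    return invert(data)


@pytest.fixture(scope="session")
def oxygenated_spectrum_snr500():
    data = simulate_decay(preset_phenotype("oxygenated"),
                          AcquisitionScheme(n_echoes=4000, noise_sd=0.002),
                          seed=7)
    return invert(data)


@pytest.fixture(scope="session")
def oxidized_spectrum():
    data = simulate_decay(preset_phenotype("oxidized"),
                          AcquisitionScheme(n_echoes=2000, noise_sd=0.0))
    return invert(data)


@pytest.fixture(scope="session")
def oxygenated_report(oxygenated_spectrum):
    return classify_peaks_rst(detect_peaks(oxygenated_spectrum))


@pytest.fixture(scope="session")
def cohort_features():
    """Default 32-subject cohort: manifest, features and binary labels."""
    manifest, decays = generate_cohort(seed=1)
    features = [
        featurize(invert(d), subject_id=r.subject_id)
        for r, d in zip(manifest.subjects, decays)
    ]
    return manifest, features, binary_disease_labels(manifest)
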