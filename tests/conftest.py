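"""Shared fixtures and the independent dense-grid oracle.

The oracle never calls the production index code: it samples the continuous
generator model on a 10,000-point grid, differentiates numerically and
locates extrema/crossings directly, so production results can be checked
against it as an independent reference.
"""

from __future__ import annotations

import numpy as np
import pytest

from cinefill import CohortSpec, generate_cohort
from cinefill.cohort import PatientTruth, VolumeModel


def dense_grid_oracle(truth: PatientTruth, n: int = 10_000) -> dict[str, float]:
    """Reference indices from dense sampling of the continuous model."""
    model = VolumeModel(truth)
    t = np.linspace(0.0, truth.rr_ms, n, endpoint=False)
    v = model.volume(t)
    es_i = int(np.argmin(v))
    es_t = float(t[es_i])
    esv = float(v[es_i])
    edv = float(np.max(v))
    sv = edv - esv
    rate = np.gradient(v, t[1] - t[0]) * 1000.0  # ml/s
    dia = t > es_t
    pfr = float(np.max(rate[dia]))
    tpfr = float(t[dia][int(np.argmax(rate[dia]))] - es_t)
    target = esv + 0.8 * sv
    cross = int(np.argmax((v >= target) & dia))
    dvr = 100.0 * (t[cross] - es_t) / (truth.rr_ms - es_t)
    return {
        "edv": edv,
        "esv": esv,
        "sv": sv,
        "pfr": pfr,
        "tpfr": tpfr,
        "dvr": dvr,
        "es_time": es_t,
    }


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical 115-patient cohort (30 phases, 2 ml noise, seed 0)."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def small_clean_cohort():
    """Ten noise-free patients spanning all grades (phantom-sized)."""
    spec = CohortSpec(
        counts={"normal": 3, "grade1": 3, "grade2": 2, "grade3": 2},
        noise_sd=0.0,
        seed=0,
    )
    return generate_cohort(spec)
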