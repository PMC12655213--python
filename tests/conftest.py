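import math

import numpy as np
import pandas as pd
import pytest

from mcubed.compartmental import DoseEvent, concentration
from mcubed.studies import load_vancomycin_studies


@pytest.fixture(scope="session")
def vanco_studies():
    return load_vancomycin_studies()


TRUE_2CMT = {"CL": 3.0, "V1": 30.0, "Q2": 7.0, "V2": 45.0}


def simulate_homogeneous(seed, n_subjects=60, omega2=0.09, sigma2=0.04,
                         theta_clcr=0.75, n_samples=4, n_doses=9,
                         sample_window=(96.0, 108.0)):
    """Two-compartment steady-state dataset from known parameters.

    Independent of the package's forward-simulation module: doses and
    observations are laid out directly, so estimation tests do not depend
    on the study-descriptor machinery.
    """
    rng = np.random.default_rng(seed)
    rows = []
    events = [DoseEvent(12.0 * i, 1000.0, 1.0) for i in range(n_doses)]
    for s in range(1, n_subjects + 1):
        clcr = rng.uniform(20.0, 150.0)
        cl_i = TRUE_2CMT["CL"] * (clcr / 75.0) ** theta_clcr \
            * math.exp(rng.normal(0.0, math.sqrt(omega2)))
        params = {**TRUE_2CMT, "CL": cl_i}
        ts = np.sort(rng.uniform(*sample_window, size=n_samples))
        conc = concentration(params, events, ts)
        base = {"ID": s, "CLCR": clcr, "BW": 65.0, "AGE": 50.0, "SEX": 1}
        for ev in events:
            rows.append({**base, "TIME": ev.time, "AMT": ev.amount,
                         "RATE": ev.rate, "EVID": 1, "MDV": 1,
                         "DV": np.nan})
        for t, c in zip(ts, conc):
            y = c * (1.0 + rng.normal(0.0, math.sqrt(sigma2)))
            rows.append({**base, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                         "EVID": 0, "MDV": 0, "DV": max(y, 1e-3)})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def homogeneous_frame():
    return simulate_homogeneous(7)
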