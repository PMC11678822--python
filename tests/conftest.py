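import numpy as np
import pandas as pd
import pytest

import bequiv as bq
from bequiv.io import CSV_COLUMNS


def make_dataset(values, grid=(0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0), lloq=0.01):
    """Build a StudyDataset from {subject: (sequence, {period: profile})}.

    ``profile`` is a sequence of concentrations aligned to ``grid``; None
    marks a BLQ sample.
    """
    rows = []
    for subject, (sequence, periods) in values.items():
        for period, profile in periods.items():
            form = bq.io.formulation_for(sequence, period)
            for t, c in zip(grid, profile):
                rows.append({
                    "subject": subject, "sequence": sequence, "period": period,
                    "formulation": form, "time_h": t,
                    "conc_ng_ml": np.nan if c is None else float(c),
                    "blq": c is None,
                })
    config = bq.StudyConfig(lloq_ng_ml=lloq, dose_mg=100.0, nominal_times_h=grid, label="toy")
    return bq.StudyDataset(records=pd.DataFrame(rows, columns=CSV_COLUMNS), config=config)


@pytest.fixture
def toy_study():
    """Four completers, noiseless-ish profiles peaking at 4 h."""
    base = [0, 10, 18, 20, 12, 5, 2, 1]
    vals = {}
    for i, (seq, scale_t, scale_r) in enumerate(
        [("TR", 1.0, 1.0), ("TR", 1.2, 1.1), ("RT", 0.9, 1.0), ("RT", 1.1, 0.95)]
    ):
        p_test = 1 if seq == "TR" else 2
        periods = {
            p_test: [c * scale_t for c in base],
            3 - p_test: [c * scale_r for c in base],
        }
        vals[f"S{i + 1}"] = (seq, periods)
    return make_dataset(vals)


@pytest.fixture
def pilot_study():
    """Seeded simulated pazopanib-like pilot (n=24, ISCV target 50%)."""
    params, var, design = bq.preset("pazopanib_200", seed=123)
    return bq.simulate_study(params, var, design, label="pilot-sim")


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
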