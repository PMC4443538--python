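import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from capsuledyn.dataset import ExpressionDataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_dataset(values, calls=None, group="immobilized", weeks=None):
    """Build a one-group ExpressionDataset from nested dicts.

    ``values``: probe -> week -> list of replicate intensities.
    ``calls``: same structure of call symbols, defaults to all "P".
    """
    probes = list(values)
    weeks = weeks or sorted(next(iter(values.values())))
    cols, meta = [], []
    for w in weeks:
        nrep = len(values[probes[0]][w])
        for r in range(1, nrep + 1):
            sid = f"{group}_w{w}_r{r}"
            cols.append(sid)
            meta.append({"sample_id": sid, "group": group, "week": w, "replicate": r})
    intens = pd.DataFrame(
        [[v for w in weeks for v in values[p][w]] for p in probes],
        index=pd.Index(probes, name="probe_id"), columns=cols, dtype=float,
    )
    if calls is None:
        call_frame = pd.DataFrame("P", index=intens.index, columns=cols)
    else:
        call_frame = pd.DataFrame(
            [[c for w in weeks for c in calls[p][w]] for p in probes],
            index=intens.index, columns=cols,
        )
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionDataset(intens, call_frame, samples)


@pytest.fixture
def small_dataset():
    """3 probes x 5 weeks x 2 replicates; one all-absent probe."""
    weeks = [1, 2, 4, 8, 16]
    values = {
        "p_live": {w: [100.0 * 2**i, 110.0 * 2**i] for i, w in enumerate(weeks)},
        "p_absent": {w: [50.0, 55.0] for w in weeks},
        "p_low": {w: [40.0, 60.0] for w in weeks},
    }
    calls = {
        "p_live": {w: ["P", "P"] for w in weeks},
        "p_absent": {w: ["A", "A"] for w in weeks},
        "p_low": {w: ["P", "A"] for w in weeks},
    }
    return build_dataset(values, calls)
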