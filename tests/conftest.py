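from __future__ import annotations

import numpy as np
import pytest

from cgmficc.ingest_qc import SLOTS_PER_DAY, DayCurve, SubjectSeries


def make_curve(
    subject_id: str,
    day: int,
    values=None,
    observed=None,
    fill_value: float = 100.0,
    n_fingersticks: int = 3,
) -> DayCurve:
    """Build a DayCurve from a sparse slot->value mapping or a full array."""
    vals = np.full(SLOTS_PER_DAY, np.nan)
    mask = np.zeros(SLOTS_PER_DAY, dtype=bool)
    if values is None:
        vals[:] = fill_value
        mask[:] = True
    elif isinstance(values, dict):
        for slot, v in values.items():
            vals[slot] = v
            mask[slot] = True
    else:
        vals[:] = np.asarray(values, float)
        mask[:] = True
    if observed is not None:
        observed = np.asarray(observed, bool)
        mask = observed
        vals = np.where(mask, vals, np.nan)
    return DayCurve(subject_id, day, vals, mask, n_fingersticks=n_fingersticks)


def make_series(subject_id: str, day_values: dict[int, np.ndarray]) -> SubjectSeries:
    curves = [make_curve(subject_id, d, values=v) for d, v in sorted(day_values.items())]
    return SubjectSeries(subject_id, curves)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_cohort(rng):
    """Four subjects x three complete days of smooth-ish random curves."""
    out = []
    for i in range(4):
        base = 90 + 10 * i + 5 * np.sin(np.linspace(0, 2 * np.pi, SLOTS_PER_DAY))
        days = {
            d + 1: base + rng.normal(0, 4, SLOTS_PER_DAY) for d in range(3)
        }
        out.append(make_series(f"P{i}", days))
    return out
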