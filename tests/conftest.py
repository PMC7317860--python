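"""Shared fixtures: small record tables and a cached synthetic bundle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from effortshift.synthetic import SyntheticConfig, generate_effort, generate_ssta


def make_records(rows) -> pd.DataFrame:
    """Effort-record table from (year, month, lat, lon, effort[, fad, free]) tuples."""
    out = []
    for row in rows:
        year, month, lat, lon, eff = row[:5]
        fad = row[5] if len(row) > 5 else 0.0
        free = row[6] if len(row) > 6 else 0.0
        out.append(
            {
                "year": year,
                "month": month,
                "lat": lat,
                "lon": lon,
                "effort_hours": eff,
                "catch_fad_t": fad,
                "catch_free_t": free,
                "fleet": "T",
            }
        )
    return pd.DataFrame(out)


def random_records(rng: np.random.Generator, n: int, years=(1991, 2017)) -> pd.DataFrame:
    """Random in-region 1-degree records for oracle comparisons."""
    return make_records(
        [
            (
                int(rng.integers(years[0], years[1] + 1)),
                int(rng.integers(1, 13)),
                float(rng.integers(-30, 29) + 0.5),
                float(rng.integers(-35, 19) + 0.5),
                float(rng.uniform(0.0, 100.0)),
                float(rng.uniform(0.0, 5.0)),
                float(rng.uniform(0.0, 5.0)),
            )
            for _ in range(n)
        ]
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic dataset shared across tests."""
    cfg = SyntheticConfig(seed=1234)
    ssta_cube, ssta_truth = generate_ssta(cfg)
    records, effort_truth = generate_effort(cfg, ssta_truth)
    return {
        "config": cfg,
        "ssta_cube": ssta_cube,
        "ssta_truth": ssta_truth,
        "records": records,
        "effort_truth": effort_truth,
    }
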