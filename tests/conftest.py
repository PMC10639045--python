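"""Shared fixtures: small synthetic cohorts and hand-built signal fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adductomics.peaks import AlignedSignals
from adductomics.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort: 2 tissues, 2 ages, 2 animals per cell."""
    cfg = SimulationConfig(
        tissues=("liver", "heart"), ages=(1.0, 26.0), n_per_cell=2, n_unnamed=6
    )
    return simulate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    """Zero-noise settings for exact truth-recovery checks."""
    return SimulationConfig(
        tissues=("liver", "heart"),
        ages=(1.0, 26.0),
        n_per_cell=2,
        n_unnamed=6,
        cv=0.0,
        noise_sd=0.0,
        uv_cv=0.0,
    )


def make_aligned(rows, sample_ids, shapes=None):
    """Build an AlignedSignals from (signal_id, prec, prod, rt, {sample: val})."""
    table_rows = []
    for sig_id, prec, prod, rt, vals in rows:
        row = {"signal_id": sig_id, "precursor_mz": prec, "product_mz": prod, "rt": rt}
        row.update(vals)
        table_rows.append(row)
    if not table_rows:
        table = pd.DataFrame(
            columns=["precursor_mz", "product_mz", "rt"] + list(sample_ids)
        )
        return AlignedSignals(table=table, sample_ids=list(sample_ids), shapes={})
    table = pd.DataFrame(table_rows).set_index("signal_id")
    for sid in sample_ids:
        if sid not in table.columns:
            table[sid] = np.nan
    table = table[["precursor_mz", "product_mz", "rt"] + list(sample_ids)]
    return AlignedSignals(table=table, sample_ids=list(sample_ids), shapes=shapes or {})


def make_meta(hydro_by_tissue, n_controls=1, n_blanks=1):
    """Sample metadata with the given hydrolysate ids per tissue."""
    rows = []
    for tissue, ids in hydro_by_tissue.items():
        for sid in ids:
            rows.append({"sample_id": sid, "cohort": "g", "tissue": tissue,
                         "age": 1.0, "sex": "F", "sample_type": "hydrolysate"})
    for i in range(n_controls):
        rows.append({"sample_id": f"ctrl{i+1}", "cohort": "g", "tissue": "none",
                     "age": np.nan, "sex": "NA", "sample_type": "intact_control"})
    for i in range(n_blanks):
        rows.append({"sample_id": f"blank{i+1}", "cohort": "g", "tissue": "none",
                     "age": np.nan, "sex": "NA", "sample_type": "blank"})
    return pd.DataFrame(rows)
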