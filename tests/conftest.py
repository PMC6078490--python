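import numpy as np
import pytest

import dungfauna as df


@pytest.fixture
def design():
    return df.DEFAULT_DESIGN


@pytest.fixture
def config():
    return df.AnalysisConfig(mc_draws=50_000, seed=11)


@pytest.fixture
def default_profile(design):
    """Noise-free profile on the study's sampling days (CV = 0)."""
    params = df.ExcretionModelParams(replicate_cv=0.0)
    return df.simulate_excretion_profile(
        params, np.asarray(design.sampling_days, dtype=float), replicates=3, seed=0
    )


def table1_disruption_pattern():
    """Per-day number of disrupted pats giving retained n = {12,11,10,10,10,12,10,11}."""
    return {0: 0, 7: 1, 14: 2, 28: 2, 56: 2, 84: 0, 112: 2, 140: 1}


@pytest.fixture
def trial_records(design):
    """A 96-pat trial, one record per pat, disruption in the study's pattern."""
    removed = table1_disruption_pattern()
    records = []
    for day in design.sampling_days:
        for p in range(1, design.pats_per_day + 1):
            records.append(
                df.EmergenceRecord(
                    pat_id=f"d{day:03d}p{p:02d}",
                    sampling_day=day,
                    order=df.DIPTERA,
                    taxon="Muscidae",
                    emergence_week=2,
                    count=3,
                    disrupted=p <= removed[day],
                )
            )
    return records
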