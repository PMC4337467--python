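import numpy as np
import pandas as pd
import pytest

import pelagia as pg


@pytest.fixture(scope="session")
def small_cfg():
    """Two-bird cohort with a shortened overwinter to keep unit tests quick."""
    return pg.SimConfig(seed=11, n_birds=2, overwinter_days=40)


@pytest.fixture(scope="session")
def bird0(small_cfg):
    """One simulated bird: true track, noisy fixes, immersion with labels."""
    track, truth = pg.simulate_track(small_cfg, 0)
    fixes = pg.observe_track(track, small_cfg, 0)
    sched = pg.activity_schedule(small_cfg, truth, pd.DatetimeIndex(track["date"]))
    series, labels, bout_truth = pg.simulate_immersion(sched, small_cfg, 0)
    return {"cfg": small_cfg, "track": track, "truth": truth, "fixes": fixes,
            "schedule": sched, "series": series, "labels": labels,
            "bout_truth": bout_truth}


@pytest.fixture(scope="session")
def bird0_budget(bird0):
    """Full immersion chain for bird0: intervals -> BEC -> bouts -> budgets."""
    iv = pg.to_intervals(bird0["series"])
    res = pg.BoutIntervalModel(iv["duration_min"].values).fit()
    bouts = pg.classify_bouts(iv, res)
    budget = pg.daily_budget(bouts, bird_id="bird00")
    return {"intervals": iv, "results": res, "bouts": bouts, "budget": budget}


def make_series(runs, sampling_interval=90, start="2008-07-01"):
    """Build an ImmersionSeries from (state, n_samples) run pairs;
    state 1 = wet, 0 = dry."""
    states = np.concatenate([np.full(n, s, dtype=np.uint8) for s, n in runs])
    return pg.ImmersionSeries(bird_id="t", sampling_interval=sampling_interval,
                              start=pd.Timestamp(start), states=states)


@pytest.fixture
def meridional_track():
    """Track moving due north from (0, 0) at 1 degree latitude per day."""
    dates = pd.date_range("2008-07-01", periods=40, freq="D")
    return pd.DataFrame({"bird_id": "m", "date": dates,
                         "lon": 0.0, "lat": np.arange(40, dtype=float)})
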