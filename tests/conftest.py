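import numpy as np
import pandas as pd
import pytest

import soarlift as sl


@pytest.fixture(scope="session")
def small_config():
    """A reduced campaign: enough segments to cluster, fast to generate."""
    return sl.SimulationConfig(n_birds=8, n_days=2, fixes_per_day=150)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(fixes, bursts, truth, dem, lst) for the reduced campaign."""
    return sl.simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def small_segment_table(small_config, small_study):
    fixes, bursts, truth, dem, lst = small_study
    segs = sl.segment_track(sl.filter_fixes(fixes), bursts=bursts)
    return sl.segment_table(segs, dem, small_config.wind)


def make_fixes(t0="2012-08-21 09:00:00", dt_s=10.0, xs=None, ys=None,
               alts=None, n=None, bird="b1", day="2012-08-21"):
    """A fix frame from coordinate arrays (or zeros of length n)."""
    if n is None:
        n = len(xs)
    xs = np.zeros(n) if xs is None else np.asarray(xs, float)
    ys = np.zeros(n) if ys is None else np.asarray(ys, float)
    alts = np.full(n, 400.0) if alts is None else np.asarray(alts, float)
    t = pd.Timestamp(t0) + pd.to_timedelta(np.arange(n) * dt_s, unit="s")
    return pd.DataFrame({"bird_id": bird, "day": day, "t": t,
                         "x": xs, "y": ys, "alt": alts})


@pytest.fixture
def flat_dem():
    return sl.RasterGrid(np.zeros((40, 40)), 100.0)


def annotate_generating_bout(table, truth):
    """Attach the generating bout id and mode to each segment row.

    Bouts are separated by gaps, so a segment's first fix falls inside
    exactly one truth bout interval (or none, for relocation fragments).
    """
    modes, bouts = [], []
    for row in table.itertuples():
        m = truth[(truth.bird_id == row.bird_id) & (truth.day == row.day)
                  & (truth.t_start <= row.t_start) & (truth.t_end >= row.t_start)]
        modes.append(m["mode"].iloc[0] if len(m) else None)
        bouts.append((row.bird_id, str(row.day), int(m["bout"].iloc[0]))
                     if len(m) else None)
    return table.assign(gen_mode=modes, gen_bout=bouts)
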