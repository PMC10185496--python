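import datetime as dt

import numpy as np
import pytest

from moontrigger import (GeneratorConfig, generate_dataset, positive_transform)
from moontrigger.synth import to_pipeline_frame


@pytest.fixture(scope="session")
def synth_dataset():
    """One default-condition synthetic dataset shared across tests."""
    cfg = GeneratorConfig(seed=11)
    sites, raster, traits, obs, truth = generate_dataset(cfg)
    return dict(cfg=cfg, sites=sites, raster=raster, traits=traits, obs=obs, truth=truth)


@pytest.fixture(scope="session")
def pipeline_frame(synth_dataset):
    df = to_pipeline_frame(synth_dataset["obs"], synth_dataset["sites"])
    y, tr = positive_transform(df["dosrtnf"])
    df = df.assign(y=y)
    return df, tr, synth_dataset["truth"]


def make_step_timeline(rng, n_nights=3):
    """Random piecewise-constant nightly series wrapped as a LightTimeline.

    Each night is 100 steps of positive step-function light; nights are
    delimited explicitly so the detector's night windows are exact.
    """
    from moontrigger.timeline import LightTimeline, NightWindow

    steps_per_night = 100
    n = n_nights * steps_per_night
    total = np.ones(n)
    for k in range(n_nights):
        base = 10 ** rng.uniform(-0.6, 2)
        levels = base * (1 + rng.choice([0, 0.02, 0.2, 1, 10], size=rng.integers(2, 8)))
        bounds = np.sort(rng.choice(np.arange(1, steps_per_night), len(levels) - 1,
                                    replace=False))
        seg = np.split(np.arange(steps_per_night), bounds)
        for lv, idx in zip(levels, seg):
            total[k * steps_per_night + idx] = lv
    times = (np.datetime64("2020-06-01T12:00:00") +
             np.arange(n) * np.timedelta64(300, "s"))
    nights = [NightWindow(dt.date(2020, 6, 1) + dt.timedelta(days=k), None,
                          k * steps_per_night, (k + 1) * steps_per_night - 1)
              for k in range(n_nights)]
    zeros = np.zeros(n)
    return LightTimeline(0.0, 0.0, times, zeros, zeros, zeros, zeros, total, nights)


def brute_force_minimum_periods(tl, tolerance_rel=0.05, min_duration=30.0):
    """Exhaustive window-scan oracle for the minimum-period detector.

    For every night, checks every [i, j] step window for (a) all steps
    within (1+tol) x the nightly minimum, (b) maximality, (c) span >=
    min_duration; independent of the implementation's single-pass scan.
    """
    from moontrigger.timeline import MinimumPeriod, STEP_MINUTES

    total = tl.total
    out = []
    for nw in tl.nights:
        if nw.i_end <= nw.i_start:
            continue
        seg = total[nw.i_start:nw.i_end + 1]
        m = seg.min()
        ok = seg <= (1 + tolerance_rel) * m
        n = len(seg)
        for i in range(n):
            for j in range(i, n):
                if not ok[i:j + 1].all():
                    break
                maximal = ((i == 0 or not ok[i - 1])
                           and (j == n - 1 or not ok[j + 1]))
                if maximal and (j - i) * STEP_MINUTES >= min_duration:
                    out.append(MinimumPeriod(nw.night_date,
                                             tl.times[nw.i_start + i],
                                             tl.times[nw.i_start + j],
                                             float((j - i) * STEP_MINUTES),
                                             float(m)))
    return out
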