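"""Correlate a declining index with a rising vaccination-style curve.

The external series is a logistic first-dose share (OWID-style 2-column
CSV would load the same way via read_external_series). A strong negative
Pearson r means the index falls as the share rises — association only,
no causal claim.
"""

from datetime import date, timedelta

import numpy as np
import pandas as pd

from negindex import (
    ExternalSeries,
    SyntheticProfile,
    align_and_correlate,
    simulate_daily_counts,
)

start = date(2020, 11, 1)
profile = SyntheticProfile(
    start=start,
    end=start + timedelta(days=179),
    tweets_per_day=5000.0,
    plateau_lambda=0.165,
    decline_start=start,
    decline_slope=-4e-4,
    seed=3,
)
series = simulate_daily_counts(profile)

days = pd.date_range(start, profile.end, freq="D")
t = np.arange(len(days), dtype=float)
share = 0.6 / (1.0 + np.exp(-(t - 90.0) / 20.0))  # logistic ramp to 60%
vaccination = ExternalSeries(pd.Series(share, index=days), label="share vaccinated")

for lag in (0, 14):
    res = align_and_correlate(series, vaccination, lag_days=lag)
    print(f"lag {lag:2d} days: Pearson r = {res.r:+.3f} over {res.n} matched days")
# r is strongly negative: the simulated negativity drops while the
# vaccination share climbs.
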