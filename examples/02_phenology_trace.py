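"""Trace the three-stage anthesis model for one cultivar in one site-year.

With flat 30/20 °C weather every day contributes 17 GDD (mean 25 °C
minus the 8 °C base), so each stage boundary can be checked by hand:
emergence at 45 GDD, Stage 1 lasting P1 = 170 GDD, the four-day Stage 2
under short days, and Stage 3 running until all TOLN leaves expand.
"""

import numpy as np

from phenoscan import CultivarParams, simulate_anthesis
from phenoscan.env import SiteYear, WeatherSeries

dates = np.arange(np.datetime64("2006-01-01"), np.datetime64("2008-01-01"))
weather = WeatherSeries(
    dates, np.full(len(dates), 30.0), np.full(len(dates), 20.0)
)
siteyear = SiteYear("FLAT", 0.0, 0.0, 2006, 100, weather)

params = CultivarParams(p1=170, p2=2.0, p2o=14.0, phint=43)
r = simulate_anthesis(siteyear, params)

print(f"emergence:         day {r.emergence_dap}  (45 GDD / 17 per day)")
print(f"end of juvenile:   day {r.end_juvenile_dap}  (+170 GDD = 10 days)")
print(f"tassel initiation: day {r.tassel_initiation_dap}  (4-day Stage 2)")
print(f"SUMDTT at TI:      {r.sumdtt_at_ti:.0f} GDD")
print(f"total leaf number: {r.toln:.2f}")
print(f"anthesis:          day {r.anthesis_dap}")
# Expected: days 3, 13, 17, SUMDTT 238, TOLN 16.07, anthesis day 45 —
# Stage 3 needs (TOLN+0.5)*43 - 238 = 474.5 GDD = 28 more days.
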