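"""Simulate one week of nightly sea-surface light at a mid-latitude reef.

Builds a 5-minute broadband timeline around the September 2020 full moon
for the Gulf of Aqaba (29.5 N) and prints the nightly minimum and the
dark window between astronomical dusk and moonrise.  The nightly minimum
sits on the 0.25 uW m^-2 dark-sky floor once the moon rises late enough.
"""

import datetime as dt

import numpy as np

from moontrigger import build_timeline, detect_minimum_periods, full_moon_instants, local_night_date

LAT, LON = 29.5, 34.95

fms = full_moon_instants(2020)
fm_night = local_night_date(LON, fms[8])  # September full moon
tl = build_timeline(LAT, LON, fm_night, fm_night + dt.timedelta(days=7), alan=None)

print(f"full-moon night: {fm_night}")
print(f"{'night':<12}{'sunset':<22}{'moonrise':<22}dark-window")
for nw in tl.nights:
    ev = nw.events
    rise = str(ev.moonrise) if ev.moonrise is not None else "--"
    gap = ""
    if ev.moonrise is not None and ev.astronomical_dusk is not None:
        mins = (ev.moonrise - ev.astronomical_dusk) / np.timedelta64(1, "m")
        gap = f"{mins:+.0f} min after astronomical dusk"
    print(f"{nw.night_date!s:<12}{ev.sunset!s:<22}{rise:<22}{gap}")

periods = detect_minimum_periods(tl, min_duration=30)
print("\nnights with an extended (>=30 min) minimum-light period:")
for p in periods:
    print(f"  {p.night_date}  {p.start} -> {p.end}  ({p.duration_min:.0f} min at "
          f"{p.level_uW:.2f} uW/m2)")
print("\nThe first such night after full moon is the modeled spawning trigger;")
print("the minimum level equals the dark-sky floor because no artificial light is present.")
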