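"""How many nights does coastal light pollution advance the spawning trigger?

Builds natural and artificially lit timelines for the mid-latitude
(29.5 N) and low-latitude (-5.06 S) demonstration reefs around the
September and March 2020 full moons, and reports the first post-full-moon
night carrying an extended minimum-light period in each.  Under the
default ALAN scenario (1e4 uW m^-2, a few times full-moon irradiance)
the artificial plateau masks both late twilight and low-altitude
moonlight, so the lit trigger fires nights earlier — by 4-5 nights in
September at mid-latitude, where the harvest-moon geometry makes
moonrise only ~30 min later each night.
"""

import datetime as dt

from moontrigger import build_timeline, default_alan_config, first_trigger_night, full_moon_instants, local_night_date

fms = full_moon_instants(2020)
sites = {"mid-latitude reef (29.5N)": (29.5, 34.95),
         "low-latitude reef (5.06S)": (-5.06, 119.3)}
months = {"March": 2, "September": 8}

for name, (lat, lon) in sites.items():
    for month, k in months.items():
        fm = local_night_date(lon, fms[k])
        a, b = fm - dt.timedelta(days=2), fm + dt.timedelta(days=16)
        nat = build_timeline(lat, lon, a, b, alan=None)
        lit = build_timeline(lat, lon, a, b, alan=default_alan_config())
        r = first_trigger_night(nat, lit, fms, min_duration=30)
        print(f"{name}, {month} 2020 (full moon night {fm}):")
        print(f"  natural trigger night : +{r.first_trigger_night_natural} after full moon")
        print(f"  lit trigger night     : +{r.first_trigger_night_lit}")
        print(f"  ALAN advances trigger : {r.advance_days} night(s)\n")

print("A positive advance means corals on lit reefs perceive the spawning cue")
print("closer to the full moon, matching the shift seen in the observation data.")
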