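"""Daily reference evapotranspiration by three methods.

Builds one summer day of weather for an arid interior site and prints the
FAO-56 Penman-Monteith, Hargreaves and Priestley-Taylor reference ET. The
values are mm of water per day that a well-watered grass surface would
lose; PM is the default driver for crop-ET simulation.
"""

import datetime as dt

from aridet import Site, WeatherDay, et0_hargreaves, et0_penman_monteith, et0_priestley_taylor

day = WeatherDay(
    date=dt.date(2010, 7, 15),
    precip=0.0,
    tmax=30.0,
    tmin=15.0,
    rh_mean=45.0,
    rh_min=25.0,
    wind_u2=2.5,
)
site = Site()  # 37.9 deg N, 1550 m: the district's location constants

print(f"Penman-Monteith : {et0_penman_monteith(day, site):.2f} mm/day")
print(f"Hargreaves      : {et0_hargreaves(day, site):.2f} mm/day")
print(f"Priestley-Taylor: {et0_priestley_taylor(day, site):.2f} mm/day")
print("A hot dry mid-July day in this climate evaporates ~6-8 mm of reference water.")
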