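"""Size one shared sensor pool for three leg sites monitored in one session.

The same circulating sensors pass the knee, shin and heel collectors, so the
pool must be as large as the most demanding site's own minimum.
"""

from bsnkit import get_scenario, multi_site_minimum, smart_sensor_selection

sites = [get_scenario(n) for n in ("runners_knee", "shin_splints", "heel_inflammation")]

for s in sites:
    result = smart_sensor_selection(s.monitoring, 100, s.segment, s.collector)
    print(f"{s.collector.site:>5}: collector {s.collector.w:>4.0f} cm -> "
          f"minimum {result.n:>2} sensors for 100 readouts")

pool = multi_site_minimum(sites, s_min=100)
print(f"\nshared pool: {pool} sensors")
# The heel's short 10 cm collector sees each sensor least often, so it sets
# the pool size; the knee and shin requirements come along for free.
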