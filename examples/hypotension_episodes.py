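"""Detect hypotension episodes in an irregularly sampled pressure signal.

Builds a 30-minute systolic-pressure recording sampled at irregular
intervals, reconstructs it at one measurement per second (last observation
carried forward), computes a baseline reference, detects episodes more than
20 % below it, and aggregates the total time spent in hypotension.
"""

import datetime as dt

from trackfeat import (
    Interval,
    aggregate_intervals,
    reference_constant,
    resample,
    threshold_episodes,
)

t0 = dt.datetime(2021, 3, 10, 8, 0, 0)
sec = lambda s: t0 + dt.timedelta(seconds=s)

# irregular monitor samples: stable around 120 mmHg, one 4-minute dip to 90
samples = [
    (sec(0), 122.0), (sec(45), 119.0), (sec(130), 121.0), (sec(300), 120.0),
    (sec(600), 90.0), (sec(690), 88.0), (sec(840), 121.0), (sec(1100), 120.0),
    (sec(1500), 118.0),
]
domain = Interval(sec(0), sec(1800))

signal = resample(samples, step=1, max_gap=600, domain=domain,
                  unit_id="proc1", track_concept="sap")
reference = reference_constant(signal, Interval(sec(0), sec(300)))
episodes = threshold_episodes(signal, "<", 0.8, reference=reference, relative=True,
                              track_concept="hypotension")
duration = aggregate_intervals(episodes, domain, "sum_duration")

print(f"reference (baseline mean over the first 5 min): {reference:.2f} mmHg")
for r in episodes.records:
    print(f"episode: [{r.start:%H:%M:%S}, {r.end:%H:%M:%S})")
print(f"total time below 80% of reference: {duration} s")
# The single planted dip (samples at 600 s and 690 s, recovery sampled at
# 840 s) yields one 240 s episode: the signal holds its last value until the
# next sample, so hypotension runs from 600 s to 840 s.
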