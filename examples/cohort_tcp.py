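"""Virtual-tumor cohort and tumor-control probability under two dose levels.

Draws a Latin-hypercube cohort against the NSCLC-like proliferation profile
(doubling time 370 days, growth fraction 23%), simulates a 4-fraction
radiotherapy schedule at 15 Gy and at 10 Gy per fraction, and compares the
Poisson TCP = exp(-N) over surviving cancer stem cells.
"""

import math

import numpy as np

from oncosim import (
    ParameterRanges,
    TreatmentSchedule,
    VirtualTumorParameters,
    fixture_path,
)
from oncosim.scenarios import (
    PhantomSpec,
    run_cohort_study,
    run_virtual_tumor,
    scale_schedule_dose,
)

ranges = ParameterRanges.from_yaml(fixture_path("ranges_nsclc.yaml"))
schedule15 = TreatmentSchedule.from_yaml(fixture_path("schedule_nsclc_radio.yaml"))
base = VirtualTumorParameters(dt=2.0)
spec = PhantomSpec(grid_n=7, radius_mm=2.5)

cohort, res15, summary = run_cohort_study(
    ranges, schedule15, n=30, seed=11, spec=spec, base=base
)
print(f"cohort: {len(cohort)} sampled, {len(cohort.retained)} retained")
from collections import Counter

for reason, count in Counter(m.exclusion for m in cohort.members
                             if m.exclusion).items():
    print(f"  excluded ({count}): {reason}")

res10 = [run_virtual_tumor(m, scale_schedule_dose(schedule15, 10.0), spec)
         for m in cohort.retained]
tcp15 = [math.exp(-r.surviving_stem) for r in res15]
tcp10 = [math.exp(-r.surviving_stem) for r in res10]
print(f"\nmedian TCP, 4 x 15 Gy: {np.median(tcp15):.6g}")
print(f"median TCP, 4 x 10 Gy: {np.median(tcp10):.6g}")
print(f"median final volume (15 Gy): {summary.volume_median:.1f} mm^3")
print("\nTCP is monotone in dose on a fixed cohort; on this desk-scale "
      "phantom the surviving stem-cell counts are tiny, so both TCPs are "
      "near 1 while their ordering reflects the dose difference.")
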