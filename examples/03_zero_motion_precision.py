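"""Zero-motion precision protocol on a rescan series.

Simulates 5 same-day scans (true migration zero), runs every scan pair
through the pipeline, and summarizes the spread of measured MTPM — the
method's precision, conventionally reported as ±1.96·SD.
"""

import numpy as np

import ctrsa

spec = ctrsa.PhantomSpec.compact()
outcome, summary = ctrsa.zero_motion_study(
    spec, ctrsa.NO_DEGRADATION, n_poses=5, seed=11)

print(f"{len(outcome.results)} pairwise analyses "
      f"({outcome.design.n} scans, all pairs), {len(outcome.failures)} failures")
for r in outcome.results:
    print(f"  pair {r.pair_id}: MTPM {r.MTPM_all:.4f} mm, TT {r.TT:.4f} mm, "
          f"TR {r.TR:.4f} deg")

print(f"\nMTPM mean {summary.mean:.4f} mm, SD {summary.sd:.4f} mm")
print(f"precision (1.96 SD): {summary.precision_1p96sd:.4f} mm")
print()
print("True migration is zero in every pair, so every MTPM value here is")
print("pure measurement error; the 1.96 SD band is the precision figure a")
print("zero-motion study would report.")
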