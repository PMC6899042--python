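"""Compare wall velocities between a 'wild-type' and a stiff-heart group.

Simulates three specimens per condition: each specimen's true peak wall
speeds are drawn within +/-10% of the condition's nominal values (biological
inter-individual variability), a short seeded video is rendered and analysed,
and the per-specimen maximum systolic speeds are compared with the
pooled-variance Student's t-test — the comparison behind bar-plot figures
with means +/- s.e.m. and significance stars.
"""

import dataclasses

import numpy as np

from cardiomvp import analyze_sequence, compare_groups, preset, render_video, suggested_roi

rng = np.random.default_rng(0)
groups = {}
for condition in ("wt_atrium", "nsh_atrium"):
    summaries = []
    for specimen in range(3):
        nominal = preset(condition, seed=specimen, duration=3.0)
        scale = rng.uniform(0.9, 1.1)
        spec = dataclasses.replace(
            nominal,
            peak_systolic_speed=scale * nominal.peak_systolic_speed,
            peak_diastolic_speed=scale * nominal.peak_diastolic_speed,
        )
        result = analyze_sequence(render_video(spec), suggested_roi(spec))
        summaries.append(result.summary)
        print(f"{condition} specimen {specimen}: true peak systolic "
              f"{spec.peak_systolic_speed:6.1f} um/s, recovered "
              f"{result.summary.max_systolic_speed:6.1f} um/s")
    groups[condition] = summaries

cmp = compare_groups(groups["wt_atrium"], groups["nsh_atrium"], metric="max_systolic_speed")
print(f"\nWT:     {cmp.mean_a:6.1f} +/- {cmp.sem_a:.1f} um/s (n={cmp.n_a})")
print(f"mutant: {cmp.mean_b:6.1f} +/- {cmp.sem_b:.1f} um/s (n={cmp.n_b})")
print(f"t = {cmp.t_statistic:.2f}, two-sided p = {cmp.p_value:.2e}, "
      f"significant at 0.05: {cmp.significant}")
print("\nA large positive t with small p says the mutant group's atrial wall "
      "moves far slower than wild type — the rigid-heart phenotype.")
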