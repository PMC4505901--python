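"""Group statistics on the packaged per-subject ratio table.

Loads the reference cohort (10 controls, 19 cerebellar-ataxia patients,
one B_r/K_r ratio per subject and task), prints group summaries, the
between-group Mann-Whitney tests, and the within-group step/pursuit range
overlap.  Controls separate the two tasks completely; patients do not,
and their pursuit ratios are far below the controls'.
"""

from wristid import compare_groups, load_reference_cohort

comp = compare_groups(load_reference_cohort())

for (group, task), s in comp.summaries.items():
    print(f"{group:8s} {task:8s} mean = {s.mean:.3f}  SD = {s.sd:.3f}  "
          f"range = [{s.min:.2f}, {s.max:.2f}]  n = {s.n}")

print()
for task, res in comp.between_groups.items():
    print(f"{task:8s} control vs patient: U = {res['U']:.1f}, "
          f"Mann-Whitney p = {res['p_mw']:.3g}, t-test p = {res['p_t']:.3g}")

print()
for group, ov in comp.task_overlap.items():
    state = "overlap" if ov.overlap else "are disjoint"
    print(f"{group}s: step and pursuit ratio ranges {state} "
          f"(intersection width {ov.width:+.2f})")
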