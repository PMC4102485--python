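"""Fit an area-proportional 3-Venn diagram to a published medical survey.

The seven quantities are the fractions of US medical trainees falling into
each overlap of three groups (awareness of a chronic-kidney-disease
complication, timely screening, timely therapy).  The fit searches for three
ellipses whose region areas are directly proportional to these quantities.
"""

from areavenn import Quantities7, fit, region_areas, write_diagram

w = Quantities7(
    {"a": 0.25, "b": 0.01, "c": 0.11, "ab": 0.10, "ac": 0.29, "bc": 0.03, "abc": 0.15}
)

result = fit(w, rerun=True)
print(f"accurate: {result.accurate}  diagError: {result.diag_error:.2e}  "
      f"iterations: {result.iterations}  reruns: {result.reruns_used}")

areas = region_areas(result.diagram)
print(f"{'region':>6} {'required share':>15} {'area share':>11}")
for lab, req in w.q.items():
    print(f"{lab:>6} {req / w.total:15.6f} {areas[lab] / areas.total:11.6f}")

out = write_diagram(result, "medical_survey.svg")
print(f"wrote {out}")
# A diagError of ~1e-7 means every region's share of the diagram is within
# one part in ten million of the share its quantity demands.
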