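"""Circles cannot draw most 3-set data accurately; ellipses usually can.

Fits the same uniform-random data twice: once with the circle-restricted
search (semi-axes locked equal, no rotations) and once with full ellipses.
"""

from areavenn import Quantities7, fit, stress, region_areas

w = Quantities7(
    {"a": 3491, "b": 3409, "c": 3503, "ab": 120, "ac": 114, "bc": 132, "abc": 126}
)

for mode in ("circles", "ellipses"):
    r = fit(w, rerun=True, mode=mode)
    s = stress(region_areas(r.diagram), w)
    print(f"{mode:>8}: diagError={r.diag_error:.2e}  stress={s:.2e}  "
          f"good={r.accurate}")
# Circles have 3 degrees of freedom per curve and plateau at diagError ~1e-2;
# ellipses (5 degrees of freedom) reach the 1e-6 goodness threshold.
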