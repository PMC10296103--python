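"""Extract ROI-wise T1 modes and MD means from a synthetic phantom.

Generates a labeled volumetric phantom with known per-ROI T1 density modes
and MD constants, runs the gray-matter-gated extraction (GM probability
> 0.40, T1 histogram mode over 500-5000 ms at 30 ms bins, MD mean within
0.0005-0.004 mm^2/s), and compares against the stored truth.
"""

import numpy as np

from cortexmicro import roi_extract, synthdata

t1_vols, md_vols, truth = synthdata.generate_phantom(seed=42)

t1_summary = roi_extract.extract_all(t1_vols, "t1")
md_summary = roi_extract.extract_all(md_vols, "md")

t1_err = np.abs(t1_summary["value"].to_numpy() - truth["t1_mode"].to_numpy())
md_err = np.abs(md_summary["value"].to_numpy() - truth["md_value"].to_numpy())

print(t1_summary.head(5).round(1).to_string(index=False))
print()
print(f"ROIs extracted:            {len(t1_summary)}")
print(f"max |T1 mode error| (ms):  {t1_err.max():.1f}  (one bin width = 30)")
print(f"max |MD mean error|:       {md_err.max():.2e} mm^2/s")
print()
print("The spline-fit histogram mode recovers each ROI's true T1 density "
      "peak to well within one 30 ms bin; MD means are exact because the "
      "phantom's MD is constant per ROI.")
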