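"""Descriptive treatment statistics on untransformed BAI.

Builds a small synthetic stand where thinning doubles growth in treated
units after each block's thinning year, then summarizes mean BAI by
status and period, the percent treated-vs-untreated difference, and the
per-tree change against the pre-treatment baseline.
"""

import numpy as np

from dendrosam import BaiSeries, TreeMeta, descriptive_bai_summary

rng = np.random.default_rng(2)
series, metas = {}, {}
for i in range(30):
    years = np.arange(1985, 2019)
    treated = i < 15
    base = rng.uniform(700, 1300)
    mult = np.where(years > 2001, 2.0 if treated else 0.9, 1.0)
    series[f"t{i}"] = BaiSeries(f"t{i}", years, base * mult * rng.normal(1, 0.12, years.size))
    metas[f"t{i}"] = TreeMeta(
        f"t{i}", "P1", "B1", "S1",
        "treated-unit" if treated else "untreated-unit",
        35.0, thin_year=2001 if treated else None,
    )

d = descriptive_bai_summary(series, metas, {"B1": 2001})
print("mean BAI (mm^2/yr) by unit status and period:")
print(d.mean_bai.round(0))
print(f"\ntreated vs untreated after thinning: {d.percent_difference_post:+.1f}%")
print("per-tree change vs own pre-treatment baseline:")
for status in d.mean_percent_change.index:
    print(f"  {status:15s} {d.mean_percent_change[status]:+.1f}% "
          f"({d.fraction_increasing[status]:.0%} of trees increasing)")
print("the generating truth doubled treated growth (+100%) and shaved "
      "untreated growth by 10%; the summary recovers both patterns")
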