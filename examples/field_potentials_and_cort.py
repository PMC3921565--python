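"""Hippocampal field-potential metrics and corticosterone contrasts.

Generates synthetic EPSP sweeps (input/output series plus paired-pulse
trials) and serum CORT values, then extracts slopes, facilitation ratios and
the group statistics.
"""

import numpy as np
import pandas as pd

from agestress import physiology as ph
from agestress.design import gen_design
from agestress.synthetic import gen_cort, gen_fp_sweeps

design = gen_design(1)
sweeps = gen_fp_sweeps(design, seed=1)

curves = []
pp_rows = []
for asw in sweeps:
    c = ph.io_curve(asw.io)
    c["animal_id"] = asw.animal_id
    curves.append(c)
    for delay, pairs in asw.pp.items():
        ratios = [ph.pp_ratio(a, b)[0] for a, b in pairs]
        pp_rows.append({"animal_id": asw.animal_id, "delay_ms": delay,
                        "pp_ratio": np.nanmean(ratios)})
curves = pd.concat(curves, ignore_index=True)

group_of = {a.animal_id: f"{a.age_group}-{a.stress_group}"
            for a in design.animals}
st = ph.io_stats(curves, group_of)
print("I/O group x step ANOVA:")
print(st["anova"][["factor", "F", "p", "significant"]].to_string(index=False))
print("\nyoung-control vs aged-control LSD at the top stimulus steps:")
print(st["lsd"].tail(4)[["step", "p", "significant"]].to_string(index=False))

pp = pd.DataFrame(pp_rows)
print("\npaired-pulse facilitation by delay (group mean ratio):")
print(pp.groupby("delay_ms").pp_ratio.mean().round(2).to_string())

cort = gen_cort(design, seed=1)
cs = ph.cort_stats(cort)
print("\nCORT age x stress ANOVA:")
print(cs["anova"][["factor", "p", "significant"]].to_string(index=False))
print(cs["lsd"][["pair", "p", "significant"]].to_string(index=False))
print("\nThe aged-control I/O depression and the young-dominated CORT stress")
print("response are the planted group effects the statistics should flag.")
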