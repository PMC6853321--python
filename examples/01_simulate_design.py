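"""Simulate a pooled-serum OCP dataset under the published study design.

Builds the 50-cell design (5 age groups x 2 genders x 5 collection periods,
154 pools, oversampled 5-15 year olds in 2006/07), simulates log-normal
concentrations from the combined age-time + age-gender generative model, and
writes the table to disk.
"""

import pooltrend as pt
from pooltrend.synthetic import study_like_params

design = pt.default_design()
print(f"design: {len(design)} cells, {sum(c.n_pools for c in design)} pools")
for period in pt.PERIODS:
    n = sum(c.n_pools for c in design if c.period == period)
    size = next(c.pool_size for c in design if c.period == period)
    print(f"  {period}: {n:3d} pools of {size} individuals")

data = pt.simulate_dataset(design, study_like_params(), seed=1)
pt.write_pooled_table(data, "pooled_data.csv", seed=1)
first = data[0]
print(f"\nwrote {len(data)} observations to pooled_data.csv")
print(f"first pool: {first.age_group} {first.gender} {first.period} "
      f"-> {first.concentration:.1f} ng/g lipid")
# Each row is one pooled measurement; concentrations are log-normal around
# the cell mean, so older groups print visibly higher values.
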