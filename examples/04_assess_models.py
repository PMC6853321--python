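"""Assess and rank the three hierarchical models.

Fits the age-time model (1), the age-gender model (2) and the combined
model (3) to the same data, then prints the diagnostics table: observed
80/90/95% predictive-interval coverage, DIC with its effective parameter
count pD, RMSE and the posterior mean of sigma.  Lower DIC = better fit
after complexity; the generating model (3) should win.
"""

import pooltrend as pt
from pooltrend.synthetic import study_like_params

data = pt.simulate_dataset(pt.default_design(), study_like_params(), seed=1)
reports = []
for spec in (1, 2, 3):
    model = pt.build_model(spec)
    draws = pt.sample_posterior(model, data, n_iter=2000, n_burnin=2000, seed=1)
    reports.append(pt.assess(draws, model, data))

print(f"{'model':>5} {'80% PI':>7} {'90% PI':>7} {'95% PI':>7} "
      f"{'DIC':>8} {'pD':>6} {'RMSE':>6} {'sigma':>6}")
for r in reports:
    print(f"{r.model_spec:>5} {r.pi_coverage[80]:7.2f} {r.pi_coverage[90]:7.2f} "
          f"{r.pi_coverage[95]:7.2f} {r.dic:8.2f} {r.p_d:6.2f} {r.rmse:6.3f} "
          f"{r.sigma_mean:6.3f}")

ranking = pt.compare_models(reports)
print(f"\nbest model by DIC: model {int(ranking.iloc[0]['model'])}")
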