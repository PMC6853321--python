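"""Stage two: fit the combined hierarchical model by Gibbs sampling.

Model 3 describes each pooled log concentration as alpha[age, gender] +
beta[age, period] with a random-walk prior on the temporal effects.  Two
chains are run from overdispersed starts; the Gelman-Rubin PSRF close to 1
for every parameter indicates convergence.
"""

import pooltrend as pt
from pooltrend.synthetic import study_like_params

data = pt.simulate_dataset(pt.default_design(), study_like_params(), seed=1)
model = pt.build_model(3)
draws = pt.sample_posterior(model, data, n_chains=2, n_iter=2000, n_burnin=2000, seed=1)

psrf = pt.gelman_rubin(draws)
print(f"{len(model.param_names)} parameters, "
      f"{draws.n_chains} chains x {draws.n_iter} kept iterations")
print(f"max PSRF {psrf['psrf'].max():.3f} (convergence threshold 1.1)")

sigma = draws.get("sigma").ravel()
print(f"observation SD sigma: posterior mean {sigma.mean():.3f} "
      f"(true value used by the simulation: 0.4)")
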