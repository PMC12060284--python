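"""Estimate the methane biodegradation half-life from tracer data.

Simulates a tritium-tracer incubation experiment (flasks sampled after
2, 4, 13, 17 and 27 days at 5 and 8.5 degC), then fits the exponential
approach-to-asymptote model by maximum likelihood and samples the
posterior by MCMC.  The printed table mirrors the standard reporting
format: point estimate, standard error and the 16-84 percentile
credible interval for each parameter.
"""

from seepfate import (TracerExperimentDesign, sample_posterior,
                      simulate_tracer_experiment)

data = simulate_tracer_experiment(TracerExperimentDesign(replicates=3), seed=7)
result = sample_posterior(data, seed=0, n_steps=4000, n_burn=1000)

print(result.summary.round(3))
s = result.summary.loc["t12_ref"]
print(f"\nHalf-life at 5 degC: {s['p50']:.1f} days "
      f"(16-84 percentile range {s['p16']:.1f}-{s['p84']:.1f} days).")
print("The half-life sets the first-order rate k1 = ln2/t12 used by the")
print("water-column fate model; the credible interval reflects both flask")
print("noise and the limited sampling schedule.")
print(f"Sampler acceptance fraction {result.acceptance_fraction:.2f}, "
      f"converged={result.converged}.")
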