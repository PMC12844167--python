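"""Uniformly sample a bacterial flux polytope with ACHR.

Extracts the microbe's submodel from the joint model (its reactions, its
interspace transports, and lumen exchanges capped at the host's maximum
secretion fluxes), then runs artificial-centering hit-and-run sampling
and validates that every sampled flux vector is a steady state within
bounds.
"""

from cogem import synthetic
from cogem.community import extract_member_submodel, merge_models
from cogem.sampling import SamplerConfig, achr_sample, validate_sample

host = synthetic.generate_host_model(seed=1)
microbe = synthetic.generate_microbe_model(
    panel=synthetic.DEFAULT_PANEL[:12],
    hard_auxotrophies=["fe3"], decoy_uptakes=["ac"],
    seed=3, model_id="AM",
)
joint = merge_models([microbe], ["biomass"], ["AM"],
                     host=host, host_biomass_id="biomass_host")
submodel = extract_member_submodel(joint, "AM")
print(f"sampling the {len(submodel.reactions)}-reaction bacterial submodel")

config = SamplerConfig(n_samples=2000, thinning=10, seed=7)
sample = achr_sample(submodel, config)
report = validate_sample(sample, submodel)
print(f"{sample.n_samples} points, max |S.v| residual "
      f"{report.max_steady_state_residual:.2e}, "
      f"max bound violation {report.max_bound_violation:.2e}")

biomass = sample.column(joint.biomass["AM"])
print(f"biomass flux over the solution space: mean {biomass.mean():.2f}, "
      f"sd {biomass.std():.2f}, range [{biomass.min():.3f}, {biomass.max():.2f}]")
print("(the mean is the typical attainable growth, not the FBA optimum)")
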