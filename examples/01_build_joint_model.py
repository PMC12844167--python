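"""Assemble a host + microbe joint model around a shared lumen.

Builds a toy host and one gut-microbe model, merges them with interspace
transport reactions coupling each member's extracellular space [e] to the
shared luminal compartment [u], and classifies every lumen metabolite as
host-specific, microbe-specific, or a co-metabolite (host-secretable AND
microbe-uptakeable — the molecules that mediate host-microbiota
metabolic interplay).
"""

from cogem import synthetic
from cogem.community import identify_co_metabolites, merge_models

host = synthetic.generate_host_model(seed=1)
microbe = synthetic.generate_microbe_model(
    panel=synthetic.DEFAULT_PANEL[:12],
    hard_auxotrophies=["fe3"],        # biomass strictly requires ferric iron
    partial_dependencies=["thm"],     # thiamin helps, low-capacity bypass exists
    decoy_uptakes=["ac", "glyc"],     # consumed but growth-irrelevant
    seed=2,
    model_id="FP",
)

joint = merge_models(
    [microbe], ["biomass"], ["FP"],
    host=host, host_biomass_id="biomass_host",
)
print(f"host: {len(host.reactions)} reactions / {len(host.metabolites)} metabolites")
print(f"microbe: {len(microbe.reactions)} reactions")
print(f"joint:  {len(joint.model.reactions)} reactions / "
      f"{len(joint.model.metabolites)} metabolites, "
      f"lumen metabolites: {len(joint.lumen_metabolites)}")
print(f"microbe biomass optimum in the joint model: "
      f"{joint.optimize_member('FP').objective_value:.2f} mmol/gDW/h")

co_mets, classes = identify_co_metabolites(joint)
print("\nlumen metabolite classes (host-secretable + microbe-uptakeable ="
      " co-metabolite):")
print(classes.to_string(index=False))
print(f"\nco-metabolites: {[c.base_id for c in co_mets]}")
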