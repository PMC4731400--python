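"""Nodule contrast: raw curves pushed through the whole pipeline.

Enables the nodule template (elevated THC and BFI, depressed scattering
on the left-lobe locations of a few subjects), simulates the raw DTOF
and g2 curves, fits everything back, and tests the nodule-index
contrast with a mixed model on the thyroid records.
"""

from thyrodos import lme_contrast, process_cohort
from thyrodos.simulate import CohortConfig, NoduleTemplate, generate_cohort

config = CohortConfig(nodule=NoduleTemplate())
cohort = generate_cohort(config, seed=1, with_curves=True)
fitted = process_cohort(cohort)

thyroid = fitted[fitted["organ"] == "thyroid"]
n_nodule = int(thyroid["nodule_index"].sum())
print(f"{len(fitted)} placements fitted; {n_nodule} thyroid records carry a nodule")

for var, unit, scale in (("THC", "uM", 1.0), ("BFI", "e-9 cm^2/s", 1e9)):
    est = lme_contrast(thyroid, var, "nodule_index")
    base = est.level_estimates["intercept"] * scale
    step = est.level_estimates["slope"] * scale
    print(f"{var}: nodule-free {base:.1f} {unit}, elevation on nodule "
          f"{step:+.1f} {unit}, p = {est.p_value:.2g} "
          f"({'significant' if est.significant else 'n.s.'})")

print()
print("A hypervascular nodule roughly doubles the local hemoglobin and")
print("triples the flow index relative to nodule-free thyroid tissue —")
print("the kind of contrast a bedside optical screen would look for.")
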