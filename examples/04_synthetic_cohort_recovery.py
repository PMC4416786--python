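"""Simulate a noisy in vivo cohort and recover Kp,uu from it.

The generator's forward model builds per-animal plasma and brain-homogenate
concentrations from a known Kp,uu; the analysis chain (dilution correction,
residual-blood correction, Kp, Kp,uu) should recover that truth up to
sampling noise at the study's group size (n = 5).
"""

import numpy as np

from brainpk.distribution import ConcentrationRecord, Genotype, analyze_animal
from brainpk.simulate import default_truth, generate_cohort

truth = default_truth(seed=42)  # default 10% CV lognormal noise
cohort = generate_cohort(truth, n_per_group=5)

drug, genotype = "verapamil", "HMDR1"
g = truth.drugs[(drug, genotype)]
sub = cohort[(cohort.drug == drug) & (cohort.genotype == genotype)]
kpuus = [
    analyze_animal(
        ConcentrationRecord(
            r.animal_id, Genotype(genotype), drug,
            r.c_plasma_ng_ml, r.c_brain_homog_ng_ml, r.homogenate_dilution,
        ),
        g.v_u_brain, g.f_u_plasma, truth.vascular,
    ).kpuu
    for r in sub.itertuples()
]
est = float(np.mean(kpuus))
print(f"true Kp,uu      = {g.kpuu:.3f}")
print(f"recovered Kp,uu = {est:.3f}  (n=5 animals, 10% CV noise)")
print(f"relative error  = {abs(est - g.kpuu) / g.kpuu:.1%}")
print()
print(
    "A single 5-animal group can miss the verapamil humanized-strain Kp,uu\n"
    "by ~10% at this noise level, as here; over many replicate cohorts the\n"
    "median recovery error drops below 5%, which the test suite checks."
)
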