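"""Process the two binding assays that feed Kp,uu.

Equilibrium dialysis gives fu,plasma as the buffer/plasma concentration
ratio per replicate; the brain-slice assay gives Vu,brain as slice uptake
per final buffer concentration, with non-viable slices (end pH < 7.25 or
high LDH release) excluded by QC.
"""

from brainpk.binding import (
    DialysisRecord,
    SliceAssayRecord,
    compute_fu_plasma,
    compute_vu_brain,
)

# triplicate dialysis of oxycodone-spiked plasma
dialysis = [
    DialysisRecord("oxycodone", f"r{i}", c_buffer, 100.0)
    for i, c_buffer in enumerate([67.0, 69.5, 67.8])
]
fu = compute_fu_plasma(dialysis)
print(f"fu,plasma = {fu.fu_mean:.3f} +/- {fu.fu_sd:.3f} (n={fu.n})")

# six slices, one rendered non-viable by low pH (excluded automatically)
slices = [
    SliceAssayRecord("oxycodone", f"s{i}", 0.021, 100.0, c_homog, 10.0, ph, ldh)
    for i, (c_homog, ph, ldh) in enumerate(
        [(37.2, 7.41, 0.04), (38.9, 7.38, 0.06), (36.5, 7.44, 0.05),
         (39.4, 7.35, 0.07), (37.0, 7.40, 0.05), (950.0, 7.10, 0.55)]
    )
]
vu = compute_vu_brain(slices)
print(f"Vu,brain  = {vu.vu_mean:.2f} ml/g  ({vu.n_pass} slices pass, {vu.n_fail} fail QC)")
print()
print(
    "The failed slice's grossly inflated signal never touches the mean;\n"
    "fu ~0.68 and Vu,brain ~3.8 ml/g are the oxycodone-like assay outputs\n"
    "that enter Kp,uu = Kp / (Vu,brain * fu)."
)
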