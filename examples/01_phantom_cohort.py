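"""Generate a small synthetic thoracic CT cohort and inspect its contents.

Each case is a CT volume in Hounsfield units with ground-truth lesion
instances, a lung mask, and per-lesion metadata (location, diameter).
Distractor structures (vessel-like tubes, fat-embedded nodules) are part
of the image but never of the ground truth — they are the false-positive
material the cascade stage is trained on.
"""

from llseg.phantom import PhantomSpec, generate_cohort

cases = generate_cohort(4, PhantomSpec(), seed=11)

for i, case in enumerate(cases):
    print(f"case {i}: shape={case.ct.shape}, spacing="
          f"({case.ct.spacing[0]:.2f}, {case.ct.spacing[1]:.2f}, {case.ct.spacing[2]:.2f}) mm")
    for m in case.lesions:
        print(f"  lesion {m.label}: {m.location}, diameter {m.diameter_mm:.1f} mm")
    print(f"  distractors: {[d.kind for d in case.distractors]}")

# Every quantity above is exact generator metadata; the lesion masks in
# case.gt_lesions carry the same instances as integer labels 1..n.
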