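"""Build the 8-block oddball design and the tone stimuli it presents.

Prints the block layout for one participant rotation, checks every
sequence against the design constraints, then synthesizes the six pitch
contours and reports their vowel-mean F0 and the divergence points of
the tonal contrasts — the time origin against which MMN latencies are
measured.
"""

from tonemmn.design import build_experiment, validate_sequence
from tonemmn.stimuli import divergence_point, mean_f0_difference, \
    synthesize_contour

plan = build_experiment(rotation_id=1, seed=2025)
print("Experiment plan (rotation 1):")
for i, (cond, seq) in enumerate(zip(plan.conditions, plan.blocks), 1):
    issues = validate_sequence(seq)
    print(f"  block {i}: {cond.block_id:<20} "
          f"{len(seq)} trials, {seq.n_deviants} deviants, "
          f"valid={not issues}")

print("\nPitch contours (vowel-mean F0):")
contours = {}
for syl in ("fu", "lu"):
    for tone in ("T1", "T4", "T6"):
        c = synthesize_contour(syl, tone)
        contours[(syl, tone)] = c
        print(f"  {syl}{tone[1]}: {c.vowel_mean_hz:6.1f} Hz")

print("\nContrast geometry:")
for syl in ("fu", "lu"):
    d16 = divergence_point(contours[(syl, "T1")], contours[(syl, "T6")])
    d46 = divergence_point(contours[(syl, "T4")], contours[(syl, "T6")])
    gap = mean_f0_difference(contours[(syl, "T1")], contours[(syl, "T6")])
    print(f"  {syl}: T1/T6 diverge at {d16:.0f} ms "
          f"(mean gap {gap:.1f} Hz); T4/T6 diverge at {d46:.0f} ms")
print("\nDivergence points are where the contours first differ; the MMN "
      "search window (100-250 ms) starts there, not at sound onset.")
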