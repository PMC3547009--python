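"""Parameter recovery and false-alarm calibration at demonstration scale.

Runs a small injected-MMN recovery study (known ground truth) and a
wave-level null calibration of the permutation test; both are scaled-up
in the test suite.
"""

from tonemmn.validation import mmn_recovery_study, null_familywise_rate

result = mmn_recovery_study(seed=0, n_participants=8, n_permutations=300)
print("Recovery study (8 participants, injected MMN -1.00 µV @ 132 ms):")
print(f"  grand-average peak:     {result.grand_peak_uv:+.2f} µV at "
      f"{result.grand_latency_ms:.0f} ms post divergence")
print(f"  template-regression amplitude: "
      f"{result.recovered_amplitude_uv:+.2f} µV")
print(f"  significant negative cluster overlapping the injection: "
      f"{result.detected} (p = {result.cluster_p})")
print("\nThe raw peak underestimates the injected amplitude because the "
      "1-20 Hz filter and between-participant latency jitter attenuate "
      "the grand average; the template fit models both and recovers the "
      "injected value.")

rate = null_familywise_rate(n_datasets=60, n_participants=12,
                            n_permutations=200, seed=1)
print(f"\nNull calibration (60 datasets, no injected effect): "
      f"family false-alarm rate = {rate:.3f} (nominal 0.05)")
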