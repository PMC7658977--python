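"""The full feedback loop: recovery from sabotaged round-1 picking.

Runs the recovery protocol — 60 micrographs, 90% of round-1 picks
replaced by random coordinates, five re-training rounds, then an F2
grid search for the final threshold — and compares the result on
held-out micrographs against a picker trained directly on ground
truth.  Takes about a minute.
"""

from emloop.protocols import recovery_experiment

result = recovery_experiment()

print("round | good classes | good particles | picks/mic | relative good")
for row in result.feedback.history:
    print(f"  {row.round_label}   | {row.good_classes:12d} | "
          f"{row.good_particles:14d} | {row.picks_per_mic:9.1f} | "
          f"{row.relative_good:.2f}")
print(f"final optimized threshold: {result.feedback.final_threshold:.2f}")
print(f"held-out F2: feedback-trained {result.f2_feedback:.3f} vs "
      f"ground-truth-trained {result.f2_supervised:.3f} "
      f"(ratio {result.f2_ratio:.2f})")
print("Despite 90% of its initial training signal being random junk, "
      "the loop recovers most of the supervised picker's quality; the "
      "relative-good column mirrors the per-round evaluation tables of "
      "feedback experiments.")
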