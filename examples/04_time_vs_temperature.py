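"""Classify abundance changes as time- or temperature-dependent.

Runs the stage-extension decision framework on the 200-protein benchmark:
each stage's end (E) is compared against its extension (X, same temperature,
more time) and the next stage's end (NE, new temperature). A significant E-X
difference reads as time-dependence, X-NE as temperature-dependence, and
only-E-NE as requiring both.
"""

from micromash import classify_all, default_program
from micromash.demo import label_agreement
from micromash.simulate import benchmark_dataset

table, truth, transition = benchmark_dataset(seed=42)
calls = classify_all(table, default_program(), level="protein", alpha=0.05)

at_transition = calls[calls["transition"] == transition]
print(f"Calls at the {transition} transition "
      f"({len(at_transition)} proteins, alpha = 0.05):")
print(at_transition["label"].value_counts().to_string())

acc = label_agreement(calls, truth, transition=transition)
print(f"\nAgreement with simulator ground truth: {100 * acc:.1f}%")
print("Half the benchmark proteins decay steadily at 63 °C (time-dependent); "
      "the other half melt between 63 and 73 °C (temperature-dependent).")
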