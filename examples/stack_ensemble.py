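"""Stack the three feature-specific base networks.

Trains one small base network per feature pairing, fits a logistic
meta rule on the validation split, and compares base and ensemble
AUROC on the test split. A few minutes on one CPU.
"""

from ppistack.experiments import stacked_experiment

result = stacked_experiment(seed=5, n_sequences=60, max_epochs=8)

for ffmod, a in enumerate(result["base_aurocs"]):
    print(f"base network ffmod {ffmod}: test AUROC {a:.3f}")
print(f"stacked ensemble (logistic rule): test AUROC {result['stacked_auroc']:.3f}")
# The ensemble should match or beat its best base network: the meta rule
# learns how much to trust each feature pairing's probability.
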