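"""Train the feedforward-network model on a small synthetic endpoint dataset.

Uses a reduced epoch count and a reduced fixture so the example runs in
seconds; the default architecture is 512/128/64 hidden units with dropout
0.2, RMSprop, and 300 epochs.
"""

from nanotess.fixtures import SyntheticRecipe, generate_fixture_set
from nanotess.modeling import DNNModel, DNNParams, cross_validate, make_split

_, dataset = generate_fixture_set(
    SyntheticRecipe(n=60, diameter_range_nm=(1.0, 1.6), ligand_count_range=(2, 8))
)
plan = make_split(dataset, seed=1)
params = DNNParams(hidden=(64, 32, 16), epochs=80, seed=1)
report = cross_validate(dataset, plan, lambda: DNNModel(params))

print(f"R2_5CV = {report.r2_cv:.3f}  RMSE_5CV = {report.rmse_cv:.3f}")
print(f"R2_val = {report.r2_val:.3f}  RMSE_val = {report.rmse_val:.3f}")
history = report.details["history"]
print(f"training loss fell from {history[0]:.3f} (epoch 1) "
      f"to {history[-1]:.3f} (epoch {len(history)})")
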