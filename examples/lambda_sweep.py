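"""Sweep the two sparsity penalties and watch accuracy collapse.

Accuracy is stable over reasonable (lambda1, lambda2) settings but falls
to the 1/7 chance level once lambda1 exceeds every atom-signal
correlation: the stage-1 loadings are all zeroed and no information
reaches the classifier.
"""

from htssr import desk_scale_config, simulate_dataset, sweep_lambdas

config = desk_scale_config(seed=0)
dataset = simulate_dataset(config)

l1_grid = [0.05, 0.5, 1.1]
l2_grid = [0.1]
grid = sweep_lambdas(config, l1_grid, l2_grid, dataset=dataset)

print("held-out accuracy per (lambda1, lambda2) cell:")
print(f"{'lambda1':>8s} | " + "".join(f"l2={l2:<8g}" for l2 in l2_grid))
for l1 in l1_grid:
    cells = "".join(f"{grid[(l1, l2)]:<11.2%}" for l2 in l2_grid)
    print(f"{l1:8g} | {cells}")
print("\nchance level for 7 balanced tasks: 14.29%")
print("unit-norm columns and unit-ball atoms bound every atom-signal "
      "correlation by 1, so lambda1 > 1 forces alpha1 = 0.")
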