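"""Scaled-down repeated-sampling learning curve with Welch tests.

Runs the evaluation protocol on a small synthetic benchmark: for each
training-set size, repeated split-train-test replicates under transfer /
scratch / pretrain-only conditions, then per-n Welch's t-tests and the
minimum n with a significant improvement over pre-training alone.
A full-size run is `ctcvision.benchmark.run_transfer_benchmark`.
"""

from ctcvision.benchmark import BenchmarkSpec, run_transfer_benchmark
import ctcvision as cv

spec = BenchmarkSpec(
    pretrain_per_class=200,
    clinical_per_class=80,
    n_train_values=(2, 10),
    n_replicates=5,
    pretrain_epochs=10,
    finetune_epochs=30,
)
curve, pretrained = run_transfer_benchmark(master_seed=0, spec=spec)

print("condition        " + "".join(f"n={n:>4d}   " for n in curve.n_train_values))
for cond in curve.accuracies:
    means = "".join(f"{curve.mean(cond, n):.3f}    " for n in curve.n_train_values)
    print(f"{cond:15s}  {means}")

for n in curve.n_train_values:
    res = curve.welch("transfer", "scratch", n)
    print(f"transfer vs scratch at n={n}: t={res.t:.2f}, df={res.df:.1f}, "
          f"p={res.p:.4f}{' *' if res.significant else ''}")

min_n = cv.min_n_significant(curve, "pretrain_only", "transfer")
print(f"smallest n with significant gain over pretrain-only: {min_n}")

# Accuracies are per-replicate test accuracies; '*' marks p < 0.05
# (two-sided Welch, no multiplicity correction).
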