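"""Generate synthetic peripheral-blood events and classify them with an SVM.

Simulates a four-population mixture (lymphocytes, neutrophils, monocytes,
debris) over six cytometry channels, splits it per class into train/test,
min-max scales the channels on the training set, trains a one-vs-one
polynomial-kernel SVM at the default (c=1, g=0.7) and prints the held-out
correctness and confusion matrix.
"""

import numpy as np

from swarmgate import (
    KernelSpec, apply_minmax, default_pbmc_mixture, evaluate, fit_minmax,
    generate, stratified_split, train_multiclass,
)

if __name__ == "__main__":
    mixture = default_pbmc_mixture()
    table = generate(mixture, 2600, seed=7)
    print(f"simulated {table.n_events} events, channels {table.channel_names}")
    print("class counts:", dict(zip(mixture.label_names, np.bincount(table.labels))))

    train, test = stratified_split(table, 10 / 13, seed=7)
    params = fit_minmax(train)
    train, test = apply_minmax(train, params), apply_minmax(test, params)

    model = train_multiclass(train, c=1.0, spec=KernelSpec("polynomial", g=0.7))
    report = evaluate(model, test)
    print(f"\nheld-out correctness {report.correctness:.4f}% "
          f"({report.n_correct}/{report.n_total}), "
          f"{report.n_support_vectors} support vectors")
    print("confusion matrix (rows = true population):")
    for name, row in zip(mixture.label_names, report.confusion):
        print(f"  {name:>11}: {row}")
    print("\nMost confusions sit between lymphocytes and debris, whose FITC/SSC "
          "clusters\noverlap by design — the error the hyperparameter tuners "
          "then reduce.")
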