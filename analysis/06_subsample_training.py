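"""Learning-curve experiment: how little training data suffices?

Subsamples the cumulative training set (all orders up to 5) to 60/40/20/10/1%
and retrains the Random Forest, with five replicates at 1%, measuring the
held-out Pearson r at a fixed test order — the data-reduction design.
"""

import warnings

import numpy as np

import ribofit as rf

from _common import BASE_SEED, outdir

build_table = __import__("importlib").import_module("05_train_and_extrapolate").build_table


def main() -> None:
    out = outdir("06_subsample")
    table = build_table()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = rf.run_prediction_experiment(
            table,
            model_kinds=["random_forest"],
            max_orders=[5],
            test_orders=[6],
            subsample_spec=rf.SubsampleSpec(),
            base_seed=BASE_SEED + 30,
            out_dir=out,
        )
    print("Order-6 Pearson r vs training-set fraction (max training order 5):")
    for frac, group in metrics.groupby("subsample_fraction"):
        rs = group["pearson_r"].to_numpy()
        extra = f" (sd {rs.std(ddof=1):.3f}, n={len(rs)})" if len(rs) > 1 else ""
        print(f"  {100 * frac:>5.0f}%: r = {rs.mean():.3f}{extra}, n_train = {int(group['n_train'].iloc[0])}")
    print(f"Outputs in {out}")


if __name__ == "__main__":
    main()
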