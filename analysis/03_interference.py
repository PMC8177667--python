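#!/usr/bin/env python
"""Capacity analysis: shared-code histograms and interference curves.

Exact enumeration over all 256 four-item sequences for the shared-code
histograms of the item-position and bi-gram-chunk codes, then simulated
learning orders for the interference curves.  The landmark numbers: a
random sequence shares exactly two item-position codes with 21% of the
space and none with 31%; learning about five sequences exhausts the
pool unaffected under item-position coding, while the bi-gram code
keeps a strictly larger untouched pool at every step.

Writes: results/interference/histogram_<model>.csv, capacity_<model>.csv.
"""

import pathlib

import seqrecode as sq

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "interference"
SEED = 77


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    space = sq.enumerate_space()
    curves = {}
    for model in ("item-position", "bigram-chunk"):
        hist = sq.shared_code_histogram(model, "ABCD", space)
        hist.to_frame().to_csv(OUT / f"histogram_{model}.csv", index=False)
        shares = ", ".join(
            f"{k}: {p * 100:.1f}%" for k, p in enumerate(hist.proportions)
        )
        print(f"{model} shared-code proportions over n={hist.counts.sum()}: "
              f"{shares}")
        curve = sq.capacity_curve(model, space, n_learn_max=10,
                                  n_replicates=500, rng_seed=SEED)
        curve.to_frame().to_csv(OUT / f"capacity_{model}.csv", index=False)
        curves[model] = curve

    u = curves["item-position"].proportion_unaffected
    exhausted = next(n for n, frac in enumerate(u) if frac <= 0.01)
    print(f"item-position code: unaffected pool falls below 1% after "
          f"{exhausted} learned sequences (500 replicates)")
    u_bg = curves["bigram-chunk"].proportion_unaffected
    print(f"bi-gram chunk code unaffected at the same point: "
          f"{u_bg[exhausted] * 100:.0f}%")
    print(f"wrote interference tables to {OUT}")


if __name__ == "__main__":
    main()
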