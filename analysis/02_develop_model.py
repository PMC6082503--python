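"""Stage 2 — model development on the training/validation splits.

Runs the genetic algorithm over the five hyperparameters (elastic-net alpha
and lambda, upweighting factor and Gensini threshold, correlation-reduction
threshold), scoring each genome by the noise-subset-weighted AUC fitness.
Refits the winning genome on the training split, selects the clinical
decision threshold on validation (sensitivity floor 0.90), and freezes the
model to JSON.  The verification split is never read.
"""

import argparse
import logging
import warnings
from pathlib import Path

from cadnet.pipeline import RunConfig, cmd_develop


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")

    config = RunConfig(seed=args.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = cmd_develop(config, args.out)

    meta = model.metadata
    print(f"GA: {meta['n_generations']} generations, best fitness {meta['best_fitness']:.4f}")
    print(f"winning genome: {model.genome.to_dict()}")
    print(
        f"frozen threshold {model.threshold:.4f} "
        f"(validation sensitivity {meta['validation_sensitivity']:.3f}, "
        f"specificity {meta['validation_specificity']:.3f})"
    )
    print(f"model written to {args.out / 'model.json'}")


if __name__ == "__main__":
    main()
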