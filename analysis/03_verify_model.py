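"""Stage 3 — blinded verification.

Applies the frozen model exactly once to the 94 held-out verification
subjects and reports the confusion matrix plus sensitivity, specificity,
NPV, PPV and AUC with 95% BCa bootstrap confidence intervals.
"""

import argparse
import logging
from pathlib import Path

from cadnet.pipeline import RunConfig, cmd_verify


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")

    config = RunConfig(seed=args.seed)
    report = cmd_verify(config, args.out)
    print(report.to_text())
    print(f"report written to {args.out / 'report.json'}")


if __name__ == "__main__":
    main()
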