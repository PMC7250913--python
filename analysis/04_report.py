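#!/usr/bin/env python
"""Render the demo figures from the analysis CSVs: Nelson-Aalen step
curves per group, per-neuron reporter trajectories, and a forest plot of
the quartile hazard ratios."""

import argparse
from pathlib import Path

from neurosurv import report

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=OUT)
    args = ap.parse_args()
    for fig in report.render_report(args.out):
        print(f"wrote {fig}")


if __name__ == "__main__":
    main()
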