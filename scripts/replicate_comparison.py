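#!/usr/bin/env python
"""Non-gating replication of the real-data method comparison.

Runs the full comparison — plain ANFIS, OLVQ1+ANFIS under each membership
family, and LVQ1+ANFIS — with 10-fold cross-validation on the UCI Parkinsons
Telemonitoring file, which the user must download separately:

    https://archive.ics.uci.edu/dataset/189/parkinsons+telemonitoring

This script is exploratory and is NOT part of the test suite or the
acceptance checks: the published figures for this comparison depend on
unstated choices (target scaling, evaluation scope, rule generation for 16
inputs, initializations), so its output is a reference point, not a target.
With 16 inputs a grid partition is infeasible (3^16 rules); experts use
scatter partitioning. Expect a run time of tens of minutes on one CPU.

Usage:
    python scripts/replicate_comparison.py --data data/parkinsons_updrs.data \
        [--target motor|total] [--seed 0] [--epochs 30] [--folds 10]
"""

from __future__ import annotations

import argparse
from dataclasses import replace

from lvqanfis import anfis, lvq, pipeline
from lvqanfis.data_io import load_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", required=True)
    ap.add_argument("--target", default="motor", choices=["motor", "total"])
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--epochs", type=int, default=30,
                    help="ANFIS epochs per expert (200 in the original setup)")
    ap.add_argument("--folds", type=int, default=10)
    args = ap.parse_args()

    table = load_table(args.data, target=args.target)
    acfg = anfis.ANFISConfig(epochs=args.epochs, rule_generation="scatter",
                             seed=args.seed)
    lcfg = lvq.LVQConfig(J=9, epochs=20, seed=args.seed)

    specs = [{"method": "anfis", "name": "ANFIS", "anfis": acfg}]
    for fam in anfis.FAMILIES:
        specs.append({"method": "olvq1_anfis",
                      "name": f"OLVQ1+ANFIS ({fam} MF)",
                      "lvq": lcfg, "anfis": replace(acfg, mf_family=fam)})
    specs.append({"method": "lvq1_anfis", "name": "LVQ1+ANFIS (gaussian MF)",
                  "lvq": lcfg, "anfis": acfg})

    reports = pipeline.compare_methods(table, specs, k=args.folds,
                                       seed=args.seed, target=args.target)
    print(pipeline.report_table(reports).to_string(index=False))


if __name__ == "__main__":
    main()
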