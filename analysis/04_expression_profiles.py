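#!/usr/bin/env python
"""Expression profiling on the synthetic qPCR data: fold changes,
ER-stress responsiveness calls, tissue-specificity classes and the
viability ratio arithmetic.

Reads the fixture Ct table (GAPDH-normalised stress timecourse emulating
the panel: BiP ~20-fold and HRD1 ~4-fold as positive controls, RNFT1 and
RNF185 ~2-fold, one non-responsive gene) and a generated 18S-normalised
tissue panel (kidney-restricted gene emulating RNF183).  Writes
results/fold_changes.tsv and results/responsiveness.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from e3screen.expression import (
    delta_delta_ct,
    responsiveness,
    tissue_profile,
    viability,
)
from e3screen.synthetic import CtEffect, make_ct_table

FIXTURE = Path("results/fixture")
GENES = ["BiP", "HRD1", "RNFT1", "RNF185", "RNF13"]

TISSUES = [
    "brain", "heart", "kidney", "liver", "lung", "muscle", "pancreas",
    "placenta", "spleen", "testis", "thymus", "colon", "ovary", "prostate",
    "intestine", "stomach", "skin", "bone_marrow", "lymph_node", "adrenal",
]


def stress_panel() -> None:
    table = pd.read_csv(FIXTURE / "ct.tsv", sep="\t")
    rows = []
    for gene in GENES:
        for sample, fc in delta_delta_ct(
            table, gene, "GAPDH", calibrator="control_0h"
        ).items():
            rows.append((gene, sample, fc.fold, fc.mean, fc.sd))
    folds = pd.DataFrame(rows, columns=["gene", "sample", "fold", "mean", "sd"])
    folds.to_csv("results/fold_changes.tsv", sep="\t", index=False)

    calls = responsiveness(table, GENES, "GAPDH")
    call_rows = []
    print("ER-stress responsiveness (both Tg and Tm required):")
    for call in calls:
        peak = {
            cond: max(res.items(), key=lambda kv: kv[1][0])
            for cond, res in call.per_condition.items()
        }
        detail = "; ".join(
            f"{cond} peak {fold:.1f}x @ {t:g}h (p_adj {p:.2g})"
            for cond, (t, (fold, p)) in peak.items()
        )
        print(f"  {call.gene}: {'RESPONSIVE' if call.responsive else 'not responsive'}"
              f" [{detail}]")
        for cond, res in call.per_condition.items():
            for t, (fold, p) in res.items():
                call_rows.append((call.gene, cond, t, fold, p, call.responsive))
    pd.DataFrame(
        call_rows,
        columns=["gene", "condition", "time_h", "fold", "p_adjusted", "responsive"],
    ).to_csv("results/responsiveness.tsv", sep="\t", index=False)


def tissue_panel() -> None:
    rng = np.random.default_rng(9)
    effects = [CtEffect("RNF183", "pool", None, 1.0, 0.1, 3)]
    for tissue in TISSUES:
        fold = 50.0 if tissue == "kidney" else float(rng.uniform(0.5, 1.5))
        effects.append(CtEffect("RNF183", tissue, None, fold, 0.1, 3))
    table, _ = make_ct_table(effects, "18S", rng)
    folds = delta_delta_ct(table, "RNF183", "18S", calibrator="pool")
    profile = {t: folds[t] for t in TISSUES}
    tau, cls = tissue_profile(profile)
    top = max(profile, key=lambda t: profile[t].fold)
    print(f"tissue panel: RNF183 tau = {tau:.3f} -> {cls} "
          f"(highest: {top}, {profile[top].fold:.1f}x the pooled reference)")


def viability_demo() -> None:
    # crystal-violet OD590 arithmetic: stressed/vehicle, as fold over mock
    mock = viability(0.30, 0.60)
    rnft1 = viability(0.45, 0.60, mock_ratio=mock)
    print(f"viability: mock Tm/vehicle ratio {mock:.2f}; "
          f"RNFT1-overexpressing cells {rnft1:.2f}-fold the mock ratio")


def main() -> None:
    Path("results").mkdir(exist_ok=True)
    stress_panel()
    tissue_panel()
    viability_demo()


if __name__ == "__main__":
    main()
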