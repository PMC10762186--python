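#!/usr/bin/env python
"""Mixed-model contrasts of call features between synthetic populations.

Contrasts each of the six features between a "natural" grunt population
and (i) a matched fictive population drawn from the same generating
parameters (no real differences) and (ii) a long-duration growl
population (real differences in duration and variability). Features are
log(1+x) transformed, animal identity is a random effect, and p-values
are BH-adjusted across contrasts. Writes results/contrasts/contrasts.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

import pagvocal as pv
from pagvocal.calls import FEATURE_NAMES
from pagvocal.synth import synth_feature_table

ROOT = Path(__file__).resolve().parent.parent / "results" / "contrasts"
SEED = 42


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    natural = synth_feature_table(
        pv.GRUNT, 40, n_animals=4, seed=SEED, source="natural"
    )
    fictive = synth_feature_table(
        pv.GRUNT, 40, n_animals=4, seed=SEED + 1, source="fictive"
    )
    growls = synth_feature_table(
        pv.GROWL, 40, n_animals=4, seed=SEED + 2, source="growl"
    )
    table = pd.concat([natural, fictive, growls], ignore_index=True)

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for feature in FEATURE_NAMES:
            for c in pv.compare_feature_groups(table, feature):
                rows.append({
                    "feature": feature, "group_a": c.group_a,
                    "group_b": c.group_b, "estimate": c.estimate,
                    "p_value": c.p_value, "p_adjusted": c.p_adjusted,
                    "method": c.method,
                })
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "contrasts.csv", index=False)

    sig = out[out["p_adjusted"] < 0.05]
    nat_fic = sig[
        sig[["group_a", "group_b"]].isin(["natural", "fictive"]).all(axis=1)
    ]
    print(f"{len(out)} contrasts; {len(sig)} significant after BH at 0.05")
    print(f"natural vs fictive (same generating spec): "
          f"{len(nat_fic)} significant differences (expect ~none)")
    with_growl = sig[(sig["group_a"] == "growl") | (sig["group_b"] == "growl")]
    print(f"contrasts involving growls: {len(with_growl)} significant "
          f"(duration/variability should differ)")


if __name__ == "__main__":
    main()
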