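#!/usr/bin/env python
"""Generate the synthetic study data every later step analyses.

Writes, under results/synthetic/:

* one WAV + ground-truth sidecar per condition — a natural-like grunt
  train (stable IGI), a hindbrain-evoked-like train (IGI rises then
  falls), a growl, a hum and a buzz, each at 10 kHz with 20 dB SNR noise;
* a multi-animal catFISH cell table CSV for two reactivation regimes
  (same call type in both periods vs. different types).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import pagvocal as pv
from pagvocal import io as pio

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20260926
SNR_DB = 20.0

CONDITIONS = {
    "natural_grunt_train": pv.BoutSpec(
        6, 0.5, igi_sd=0.02, igi_profile="stable", call_spec=pv.GRUNT
    ),
    "vpp_like_grunt_train": pv.BoutSpec(
        6, 0.5, igi_sd=0.02, igi_profile="rise_fall", call_spec=pv.GRUNT
    ),
    "growl": pv.BoutSpec(1, 0.5, call_spec=pv.GROWL),
    "hum": pv.BoutSpec(1, 0.5, call_spec=pv.HUM),
    "buzz": pv.BoutSpec(1, 0.5, call_spec=pv.BUZZ),
}

# Two-period activation regimes: repeating the same call type in both
# periods reactivates most period-2 cells; switching call types shares
# only part of the population.
CATFISH_REGIMES = {
    "same_type": pv.CatfishSpec(400, p1=0.5, p2=0.5, overlap=0.9),
    "cross_type": pv.CatfishSpec(400, p1=0.5, p2=0.5, overlap=0.65),
}
N_ANIMALS = 5


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (name, spec) in enumerate(CONDITIONS.items()):
        trace, truths, igis = pv.synth_bout(spec, seed=SEED + i)
        trace = pv.add_noise(trace, SNR_DB, seed=SEED + 100 + i)
        pio.write_trace(trace, OUT / f"{name}.wav")
        pio.write_ground_truth(truths, OUT / f"{name}.truth.csv")
        pd.DataFrame({"igi_s": igis}).to_csv(
            OUT / f"{name}.igi.csv", index=False
        )
        n_pulses = sum(len(t) for t in truths)
        print(f"{name}: {len(truths)} calls, {n_pulses} pulses, "
              f"SNR {SNR_DB:.0f} dB -> {name}.wav")

    frames = []
    for regime, spec in CATFISH_REGIMES.items():
        for a in range(N_ANIMALS):
            cells = pv.synth_catfish_cells(spec, seed=SEED + 200 + hash(regime) % 97 + a)
            cells["animal_id"] = f"{regime}_fish{a}"
            cells["regime"] = regime
            frames.append(cells)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(OUT / "catfish_cells.csv", index=False)
    print(f"catFISH: {len(table)} cells, {N_ANIMALS} animals x "
          f"{len(CATFISH_REGIMES)} regimes -> catfish_cells.csv")


if __name__ == "__main__":
    main()
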