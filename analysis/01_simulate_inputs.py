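#!/usr/bin/env python
"""Generate the study inputs: two synthetic arterial input functions and an
example bank of noisy two-tissue tissue curves on the clinical schedule.

Writes results/inputs/aif_I.csv, aif_II.csv, an example TAC bank for grid
combination 1, and a manifest describing the simulation conditions.
"""

import json
from pathlib import Path

import numpy as np

import fetkin as fk

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    schedule = fk.clinical_schedule()
    print(f"clinical schedule: {schedule.n} frames, {schedule.total_end_s / 60:.0f} min")

    for aif_type in ("I", "II"):
        aif = fk.make_aif(aif_type, peak=100.0, schedule=schedule)
        fk.write_curve_csv(OUT / f"aif_{aif_type}.csv", aif)
        print(f"AIF type {aif_type}: first frame {aif.values[0]:6.2f}, "
              f"peak {aif.peak:.1f} (frame {aif.values.argmax() + 1}), "
              f"40-min tail {aif.values[-1] / aif.peak * 100:.0f}% of peak")

    truth = fk.table3_combinations()[0]
    aif = fk.make_aif("I", peak=100.0, schedule=schedule)
    noise = fk.NoiseModel(snr=100)
    print(f"\nnoise: SNR 100 -> sigma = {noise.sigma(aif.peak):.2f} (activity units)")
    bank = OUT / "tac_bank_comb1"
    bank.mkdir(exist_ok=True)
    for rep in range(20):
        tac = fk.simulate_tac(truth, aif, schedule, noise=noise, rng=rep)
        fk.write_curve_csv(bank / f"tac_{rep:03d}.csv", tac)
    (OUT / "manifest.json").write_text(json.dumps({
        "schedule": json.loads(schedule.to_json()),
        "aif_peak": 100.0,
        "snr": 100.0,
        "combination_1": {k: getattr(truth, k) for k in truth.free_names},
        "bank_replicates": 20,
    }, indent=1))
    print(f"wrote AIFs and a 20-replicate example TAC bank under {OUT}")


if __name__ == "__main__":
    main()
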