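#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/simulated/:
  titration.csv          dominant-negative titration at the reported (n, s)
  fret/<scenario>/       three-channel TIFF image sets + ground_truth.json
  lipid_traces.csv       dequenching traces across mixing extents
  syncytia_counts.csv    Poisson per-field syncytial-nucleus counts
"""

import json
from pathlib import Path

import pandas as pd

from fastfuse.io import write_fret_tiffs, write_titration_csv
from fastfuse.stoichiometry import StoichModel
from fastfuse.synthetic import (
    simulate_fret_images,
    simulate_field_counts,
    simulate_lipid_trace,
    simulate_titration,
)

SEED = 20260926
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
REPORTED = StoichModel(n=8.74, s=5.17)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    curve = simulate_titration(REPORTED, noise_sd=0.03, replicates=1,
                               experiments=3, seed=SEED)
    write_titration_csv(curve, OUT / "titration.csv")
    print(f"titration: {len(curve.points)} points across 3 experiments "
          f"from (n={REPORTED.n}, s={REPORTED.s}), noise sd 0.03")

    scenarios = ("donor_only", "acceptor_only", "interacting",
                 "non_interacting", "diffuse_depleted")
    for k, scenario in enumerate(scenarios):
        sets, truth = simulate_fret_images(scenario, n_images=2, seed=SEED + k)
        d = OUT / "fret" / scenario
        for s in sets:
            write_fret_tiffs(s, d)
        (d / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        print(f"fret/{scenario}: {len(sets)} image sets (256x256, 3 channels)")

    rows = []
    truth = {"seed": SEED, "traces": []}
    for i, extent in enumerate((0.1, 0.2, 0.4, 0.8)):
        t = simulate_lipid_trace(rate=0.01, extent=extent, f0=100.0, f_max=600.0,
                                 noise_sd=2.0, seed=SEED + 10 + i,
                                 label=f"extent_{extent}")
        truth["traces"].append({"label": t.label, "extent": extent})
        rows += [{"time_s": tt, "intensity": ii, "label": t.label}
                 for tt, ii in zip(t.time, t.intensity)]
    pd.DataFrame(rows).to_csv(OUT / "lipid_traces.csv", index=False)
    (OUT / "lipid_ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    print(f"lipid traces: {len(truth['traces'])} doses, 120 samples each")

    counts = simulate_field_counts(mean_count=20.0, seed=SEED + 20)
    pd.DataFrame(
        [{"experiment": e, "field": i + 1, "count": c}
         for e, cs in counts.items() for i, c in enumerate(cs)]
    ).to_csv(OUT / "syncytia_counts.csv", index=False)
    print("syncytia counts: 5 fields x 3 experiments, Poisson mean 20")


if __name__ == "__main__":
    main()
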