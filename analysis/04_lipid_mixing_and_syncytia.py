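#!/usr/bin/env python
"""Lipid-mixing percentages per dose and the syncytial-index summary.

Reads the simulated dequenching traces and per-field nucleus counts from
results/simulated/ (run 01_simulate_inputs.py first), normalizes each trace
between its baseline F0 and the fully dequenched F_MAX reference, and
summarizes syncytial counts as mean +/- SEM propagated within and across
experiments.  Writes results/assays.json.
"""

import json
from pathlib import Path

from fastfuse.assay_stats import percent_lipid_mixing, syncytial_index
from fastfuse.io import read_counts_csv, read_trace_csv, write_report

ROOT = Path(__file__).resolve().parent.parent / "results"
F0, F_MAX = 100.0, 600.0  # baseline and reference-liposome intensities


def main() -> None:
    traces = read_trace_csv(ROOT / "simulated" / "lipid_traces.csv")
    truth = json.loads((ROOT / "simulated" / "lipid_ground_truth.json").read_text())
    extents = {t["label"]: t["extent"] for t in truth["traces"]}
    mixing = []
    for t in traces:
        r = percent_lipid_mixing(t, F0, F_MAX)
        mixing.append({"label": t.label, "endpoint_percent": r.endpoint,
                       "true_extent_percent": 100.0 * extents[t.label]})
        print(f"{t.label}: endpoint %LM = {r.endpoint:.1f} "
              f"(generating extent {100 * extents[t.label]:.0f}%)")

    counts = read_counts_csv(ROOT / "simulated" / "syncytia_counts.csv")
    idx = syncytial_index(counts)
    print(f"syncytial index = {idx.mean:.2f} +/- {idx.sem:.2f} "
          f"({idx.n_experiments} experiments, 5 fields each)")

    write_report(
        {"lipid_mixing": mixing,
         "syncytial_index": {"mean": idx.mean, "sem": idx.sem,
                             "per_experiment_mean": idx.per_experiment_mean,
                             "per_experiment_sem": idx.per_experiment_sem}},
        ROOT / "assays.json",
    )
    print(f"wrote {ROOT / 'assays.json'}")


if __name__ == "__main__":
    main()
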