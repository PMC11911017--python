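"""Aggregate and report: correlation screen, relDis histogram, recovery.

Reads the tables written by 02, reports the correlation summary and
per-species centering percentages, exports a histogram of the relative
distances (CSV), and — because the simulated study has a truth sidecar —
measures how often the pipeline's highest-probability interval contains the
generating density's true mode.

    python analysis/03_summarize.py
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

root = Path(__file__).resolve().parents[1] / "results"
results = pd.read_csv(root / "study" / "results.csv")
summary = json.loads((root / "study" / "summary.json").read_text())
truths = {
    (t["species"], t["variable"]): t
    for t in json.loads((root / "simulation" / "truth.json").read_text())
}

analyzed = results[~results["excluded"]]
corr = summary["correlation_summary"]
print(f"pairwise |r| over {corr['n_pairs']} pairs: "
      f"mean {corr['mean_abs_r']:.3f}, median {corr['median_abs_r']:.3f}, "
      f"{corr['n_below_half']} below 0.5, {corr['n_at_or_above_half']} at/above")

pct = summary["per_species_centered_pct"]
print(f"per-species centered percentage: mean {np.mean(list(pct.values())):.1f}%, "
      f"range {min(pct.values()):.1f}-{max(pct.values()):.1f}%")

edges = np.arange(-50.0, 55.0, 5.0)
counts, _ = np.histogram(analyzed["rel_dis"], bins=edges)
hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
hist.to_csv(root / "study" / "rel_dis_histogram.csv", index=False)
print(f"relDis histogram ({len(analyzed)} analyzed combinations) -> "
      f"{root / 'study' / 'rel_dis_histogram.csv'}")

hits = sum(
    1
    for _, row in analyzed.iterrows()
    if row["xL"] <= truths[(row["species"], row["variable"])]["true_mode"] <= row["xU"]
)
print(f"true generating mode inside the recovered HPI: "
      f"{hits}/{len(analyzed)} ({100 * hits / len(analyzed):.1f}%)")
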