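"""Summarize endpoints across laboratories and derive discriminating
concentrations.

Reads the fitted endpoint table, reports the species-level LC50 and LC99
(mean of laboratory medians, with the overall min-max range), compares them
against the generating curve, and prints the discriminating concentration
as twice the LC99, rounded to two significant figures.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from bottlebioassay.endpoints import round_sig

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frame = pd.read_csv(OUT / "endpoints.csv")
    truth = json.loads((OUT / "ground_truth.json").read_text())
    base = truth["base_curve"]
    true_lc50 = float(np.exp(base["C"]))
    true_lc99 = float(np.exp(base["C"]) * 99.0 ** (1.0 / base["B"]))

    species = frame[frame.level == "species"]
    rows = []
    for q, true_value in [(0.50, true_lc50), (0.99, true_lc99)]:
        row = species[species.q == q].iloc[0]
        rows.append({
            "q": q, "estimate": row.value, "range_low": row.range_low,
            "range_high": row.range_high, "truth": true_value,
            "rel_error_pct": 100 * abs(row.value - true_value) / true_value,
        })
        print(f"LC{int(q * 100)}: {row.value:.3f} "
              f"(range {row.range_low:.3f}-{row.range_high:.3f}) µg/bottle; "
              f"truth {true_value:.3f}, error {rows[-1]['rel_error_pct']:.1f}%")

    lc99 = rows[1]["estimate"]
    dc = round_sig(2.0 * lc99, 2)
    print(f"discriminating concentration (2 x LC99, 2 s.f.): {dc} µg/bottle")
    summary = pd.DataFrame(rows)
    summary["dc_twice_lc99"] = dc
    summary.to_csv(OUT / "endpoint_summary.csv", index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
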