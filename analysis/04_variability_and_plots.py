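"""Report within-bioassay variability and draw the concentration-response
panels.

Prints the laboratory- and species-level variability (median over posterior
iterations of the mean absolute deviation between observed points and the
fitted curve, in percentage points) and regenerates the fitted panels with
min-max ribbons under results/figures/.
"""

from pathlib import Path

import pandas as pd

from bottlebioassay import MCMCConfig, analyse_campaign, read_bioassay_csv
from bottlebioassay.plotting import plot_campaign

SEED = 20230302  # same fits as 02_fit_curves
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    variability = pd.read_csv(OUT / "variability.csv")
    for _, row in variability.iterrows():
        where = row.institution if row.level == "institution" else "species mean"
        print(f"{where}: variability {row.variability_pct:.2f} pp "
              f"[{row.ci_low:.2f}, {row.ci_high:.2f}]")

    ds = read_bioassay_csv(OUT / "bioassays.csv")
    result = analyse_campaign(ds, config=MCMCConfig(seed=SEED), quantiles=(0.50,))
    written = plot_campaign(result.scopes, OUT / "figures")
    for path in written:
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
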