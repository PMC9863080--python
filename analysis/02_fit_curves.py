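"""Fit the Bayesian concentration-response model to the simulated campaign.

Runs quality control, fits one pooled curve per laboratory plus a curve per
individual bioassay (for the min-max uncertainty ranges), and writes the
endpoint, variability and QC tables under results/, together with the
posterior draws of every pooled fit.
"""

from pathlib import Path

from bottlebioassay import MCMCConfig, analyse_campaign, read_bioassay_csv

SEED = 20230302
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = read_bioassay_csv(OUT / "bioassays.csv")
    result = analyse_campaign(ds, config=MCMCConfig(seed=SEED), quantiles=(0.50, 0.99))

    for s in result.scopes:
        slug = s.scope["institution"].replace(" ", "-")
        s.pooled.save(OUT / f"draws_{slug}.csv", OUT / f"fit_{slug}.json")
    result.endpoint_frame().to_csv(OUT / "endpoints.csv", index=False, float_format="%.6g")
    result.variability_frame().to_csv(OUT / "variability.csv", index=False, float_format="%.6g")
    result.qc_frame().to_csv(OUT / "qc_report.csv", index=False)

    print(f"QC: {len(result.qc_reports)} bioassays, "
          f"{sum(r.status.value.startswith('accepted') for r in result.qc_reports)} accepted")
    for s in result.scopes:
        lc50 = next(e for e in s.endpoints if e.quantile_q == 0.50)
        print(f"{s.scope['institution']}: LC50 = {lc50.value:.3f} "
              f"(range {lc50.range_low:.3f}-{lc50.range_high:.3f}) µg/bottle, "
              f"converged={s.pooled.converged}")


if __name__ == "__main__":
    main()
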