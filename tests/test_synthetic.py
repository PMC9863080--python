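"""Synthetic campaign generator: design arithmetic, determinism, convergence
of empirical rates to the generating curve, and overdispersion behaviour."""

import numpy as np
import pytest

from bottlebioassay import (
    CampaignDesign,
    EndpointType,
    QCStatus,
    TrueCurve,
    apply_qc,
    compute_oi,
    mortality_curve,
    read_bioassay_csv,
    simulate_bioassay,
    simulate_campaign,
    simulate_oviposition,
    write_bioassay_csv,
)
from bottlebioassay.synthetic import campaign_curves, design_from_config, perturb_curve


class TestDesign:
    def test_concentrations_must_increase_and_exclude_zero(self):
        with pytest.raises(ValueError):
            CampaignDesign(concentrations=(1.0, 1.0, 3.0))
        with pytest.raises(ValueError):
            CampaignDesign(concentrations=(0.0, 1.0))

    def test_duplicate_lab_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CampaignDesign(laboratories=(("lab_1", 0.0), ("lab_1", 0.1)))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "design.yaml"
        path.write_text(
            "concentrations: [0.5, 1.0, 2.0]\n"
            "n_per_concentration: 20\n"
            "replicates_per_concentration: 2\n"
            "n_control: 1\n"
            "n_bioassays: 2\n"
            "overdispersion_rho: 0.05\n"
            "laboratories: [[labX, 0.0], [labY, 0.1]]\n"
        )
        design = design_from_config(path)
        assert design.concentrations == (0.5, 1.0, 2.0)
        assert design.laboratories == (("labX", 0.0), ("labY", 0.1))


class TestSimulateBioassay:
    def test_empirical_rate_matches_curve_at_large_n(self):
        # law of large numbers at three concentrations, three seeds
        curve = TrueCurve(3, 0, 1, 0)
        design = CampaignDesign(
            concentrations=(0.5, 1.0, 2.0), n_per_concentration=1_000_000,
            replicates_per_concentration=1, n_control=1, n_bioassays=1,
        )
        for seed in (1, 2, 3):
            ds = simulate_bioassay(curve, design, seed=seed)
            for r in ds:
                if r.concentration == 0:
                    continue
                p = mortality_curve(curve, r.concentration)
                tol = 3 * np.sqrt(0.25 / r.n_exposed)
                assert abs(r.n_responded / r.n_exposed - p) < tol

    def test_zero_background_controls_have_no_deaths(self):
        ds = simulate_bioassay(TrueCurve(3, 0, 1, 0), CampaignDesign(), seed=4)
        controls = [r for r in ds if r.is_control]
        assert controls and all(r.n_responded == 0 for r in controls)

    def test_same_seed_byte_identical_csv(self, tmp_path):
        design = CampaignDesign(overdispersion_rho=0.08)
        for i in (1, 2):
            ds = simulate_bioassay(TrueCurve(3, 0, 1, 0.03), design, seed=9)
            write_bioassay_csv(ds, tmp_path / f"run{i}.csv")
        assert (tmp_path / "run1.csv").read_bytes() == (tmp_path / "run2.csv").read_bytes()

    def test_row_count_matches_design(self, step2_design):
        ds = simulate_bioassay(TrueCurve(3, 0, 1, 0.03), step2_design, seed=1)
        assert len(ds) == step2_design.rows_per_lab == (6 * 4 + 2) * 3

    def test_overdispersion_inflates_between_replicate_variance(self):
        # >= 200 replicates at a single mid-curve concentration
        curve = TrueCurve(3, 0, 1, 0)
        kwargs = dict(
            concentrations=(1.0,), n_per_concentration=50,
            replicates_per_concentration=200, n_control=1, n_bioassays=1,
        )
        def replicate_var(rho, seed):
            ds = simulate_bioassay(curve, CampaignDesign(overdispersion_rho=rho, **kwargs), seed=seed)
            rates = [r.n_responded / r.n_exposed for r in ds if not r.is_control]
            return np.var(rates)
        assert replicate_var(0.15, 21) > replicate_var(0.0, 21)


class TestSimulateCampaign:
    def test_row_count_closed_form(self):
        design = CampaignDesign(laboratories=tuple((f"lab_{i}", 0.0) for i in range(3)))
        curves = {lab: TrueCurve(3, 0, 1, 0.03) for lab, _ in design.laboratories}
        ds = simulate_campaign(curves, design, seed=5)
        assert len(ds) == 3 * design.rows_per_lab
        assert {r.institution for r in ds} == {"lab_0", "lab_1", "lab_2"}

    def test_single_lab_reduces_to_simulate_bioassay(self):
        design = CampaignDesign()
        curve = TrueCurve(3, 0, 1, 0.03)
        campaign = simulate_campaign({"lab_1": curve}, design, seed=6)
        solo = simulate_bioassay(
            curve, design, np.random.SeedSequence(6).spawn(1)[0], labels={"institution": "lab_1"}
        )
        assert campaign.records == solo.records

    def test_zero_perturbation_scale_shares_true_lc50(self):
        design = CampaignDesign(laboratories=(("a", 0.0), ("b", 0.0)))
        curves = campaign_curves(TrueCurve(3, 0.4, 1, 0.02), design, seed=7)
        assert curves["a"] == curves["b"]

    def test_perturbation_moves_parameters(self):
        rng = np.random.default_rng(0)
        base = TrueCurve(3, 0, 1, 0.03)
        shifted = perturb_curve(base, 0.3, rng)
        assert shifted.B != base.B and shifted.C != base.C

    def test_generated_campaign_survives_qc_and_round_trip(self, tmp_path):
        design = CampaignDesign(laboratories=(("a", 0.1), ("b", 0.1)))
        curves = campaign_curves(TrueCurve(3, 0, 1, 0.03), design, seed=8)
        ds = simulate_campaign(curves, design, seed=8)
        path = tmp_path / "campaign.csv"
        write_bioassay_csv(ds, path)
        assert read_bioassay_csv(path).records == ds.records
        _, reports = apply_qc(ds)
        assert all(r.status != QCStatus.unevaluable for r in reports)


class TestSimulateOviposition:
    def test_control_non_laying_matches_background(self):
        design = CampaignDesign(
            concentrations=(1e-6,), n_per_concentration=50_000,
            replicates_per_concentration=1, n_control=1, n_bioassays=1,
        )
        ds = simulate_oviposition(TrueCurve(2, 2, 1, 0), 0.7, design, seed=11, survival_rate=1.0)
        ctrl = next(r for r in ds if r.is_control)
        assert ctrl.endpoint_type == EndpointType.oviposition
        assert ctrl.n_responded / ctrl.n_chambered == pytest.approx(0.3, abs=0.01)

    def test_saturating_concentration_inhibits_all(self):
        design = CampaignDesign(
            concentrations=(1e9,), n_per_concentration=5_000,
            replicates_per_concentration=1, n_control=1, n_bioassays=1,
        )
        ds = simulate_oviposition(TrueCurve(2, 2, 1, 0), 0.7, design, seed=12, survival_rate=1.0)
        treated = next(r for r in ds if not r.is_control)
        assert treated.n_responded / treated.n_chambered == pytest.approx(1.0, abs=0.01)

    def test_oi_at_curve_midpoint_is_fifty_percent(self):
        # at x = e^C with E=1 the corrected non-laying rate is 1/2, so the
        # laying rate is half the control's and OI ~ 50%
        C = 1.0
        design = CampaignDesign(
            concentrations=(np.exp(C),), n_per_concentration=200_000,
            replicates_per_concentration=1, n_control=1, n_bioassays=1,
        )
        ds = simulate_oviposition(TrueCurve(3, C, 1, 0), 0.8, design, seed=13, survival_rate=1.0)
        ctrl = next(r for r in ds if r.is_control)
        treated = next(r for r in ds if not r.is_control)
        laying_ctrl = 1 - ctrl.n_responded / ctrl.n_chambered
        laying_treated = 1 - treated.n_responded / treated.n_chambered
        assert compute_oi(laying_treated, laying_ctrl) == pytest.approx(50.0, abs=1.5)
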