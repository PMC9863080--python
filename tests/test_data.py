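"""Data model, CSV interchange, pooling, QC and endpoint arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bottlebioassay import (
    BioassayDataset,
    BioassayRecord,
    EndpointType,
    QCStatus,
    abbott_correct,
    apply_qc,
    compute_oi,
    pool_replicates,
    read_bioassay_csv,
    write_bioassay_csv,
)
from bottlebioassay.data import (
    BioassayFormatError,
    BioassayValidationError,
    EmptyDatasetError,
    GroupingError,
    UndefinedCorrectionError,
    UndefinedOIError,
)

from conftest import CSV_HEADER, make_csv


def rec(conc, n, y, *, bid="a1", rid="r1", endpoint=EndpointType.mortality, chambered=None):
    return BioassayRecord(
        institution="labA", country="SIM", species="An. gambiae", strain="Kisumu",
        insecticide="clothianidin", endpoint_type=endpoint, bioassay_id=bid,
        replicate_id=rid, concentration=conc, n_exposed=n, n_responded=y,
        n_chambered=chambered, recording_time_h=24,
    )


class TestReadWrite:
    def test_reads_three_row_fixture(self, tiny_csv):
        ds = read_bioassay_csv(tiny_csv)
        assert len(ds) == 3
        assert sorted(r.concentration for r in ds) == [0.0, 1.0, 10.0]
        assert ds.records[1].n_responded == 12

    def test_row_validation_error_carries_row_number(self, tmp_path):
        path = make_csv(tmp_path, [
            "labA,SIM,An. gambiae,Kisumu,clothianidin,mortality,a1,r1,1,25,30,,24",
        ])
        with pytest.raises(BioassayValidationError, match="row 2"):
            read_bioassay_csv(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(CSV_HEADER.replace(",n_responded", "") + "\n" + "a,b,c,d,e,mortality,a1,r1,1,25,,24\n")
        with pytest.raises(BioassayFormatError, match="n_responded"):
            read_bioassay_csv(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(EmptyDatasetError):
            read_bioassay_csv(path)
        path.write_text(CSV_HEADER + "\n")
        with pytest.raises(EmptyDatasetError):
            read_bioassay_csv(path)

    def test_round_trip_identity(self, tmp_path, tiny_csv):
        ds = read_bioassay_csv(tiny_csv)
        out = tmp_path / "roundtrip.csv"
        write_bioassay_csv(ds, out)
        again = read_bioassay_csv(out)
        assert again.records == ds.records

    def test_round_trip_preserves_fractional_concentrations(self, tmp_path):
        ds = BioassayDataset([rec(0.123456789012, 25, 3), rec(0.0, 25, 0, rid="c1")])
        out = tmp_path / "frac.csv"
        write_bioassay_csv(ds, out)
        back = read_bioassay_csv(out)
        assert back.records[0].concentration == pytest.approx(0.123456789012, rel=1e-12)


class TestRecordInvariants:
    def test_responded_cannot_exceed_exposed(self):
        with pytest.raises(BioassayValidationError):
            rec(1.0, 25, 26)

    def test_oviposition_requires_chambered_and_orders_counts(self):
        with pytest.raises(BioassayValidationError):
            rec(1.0, 25, 5, endpoint=EndpointType.oviposition)
        with pytest.raises(BioassayValidationError):
            rec(1.0, 25, 15, endpoint=EndpointType.oviposition, chambered=10)
        ok = rec(1.0, 25, 9, endpoint=EndpointType.oviposition, chambered=10)
        assert ok.denominator == 10

    def test_negative_concentration_rejected(self):
        with pytest.raises(BioassayValidationError):
            rec(-1.0, 25, 0)


class TestPoolReplicates:
    def test_four_replicates_of_twentyfive(self):
        group = [rec(1.0, 25, d, rid=f"r{i}") for i, d in enumerate([5, 7, 6, 4])]
        assert pool_replicates(group) == (100, 22)

    def test_single_record_identity(self):
        assert pool_replicates([rec(1.0, 25, 0)]) == (25, 0)

    def test_oviposition_uses_chambered_denominator(self):
        group = [
            rec(1.0, 25, 9, rid="r1", endpoint=EndpointType.oviposition, chambered=10),
            rec(1.0, 25, 8, rid="r2", endpoint=EndpointType.oviposition, chambered=8),
        ]
        assert pool_replicates(group) == (18, 17)

    def test_order_invariant(self):
        group = [rec(1.0, 25, d, rid=f"r{i}") for i, d in enumerate([5, 7, 6, 4])]
        assert pool_replicates(group) == pool_replicates(group[::-1])

    def test_mixed_endpoints_rejected(self):
        group = [rec(1.0, 25, 5), rec(1.0, 25, 5, rid="r2", endpoint=EndpointType.oviposition, chambered=20)]
        with pytest.raises(GroupingError):
            pool_replicates(group)


def bioassay(bid, control_dead, *, n_ctrl=50, endpoint=EndpointType.mortality, chambered_rate=None):
    """One bioassay: a control of n_ctrl and two treated replicates."""
    if endpoint == EndpointType.mortality:
        ctrl = [rec(0.0, n_ctrl, control_dead, bid=bid, rid="c1")]
        treat = [rec(1.0, 25, 20, bid=bid, rid="r1"), rec(10.0, 25, 24, bid=bid, rid="r2")]
    else:
        ctrl = [rec(0.0, n_ctrl, control_dead, bid=bid, rid="c1", endpoint=endpoint, chambered=n_ctrl)]
        treat = [rec(1.0, 25, 18, bid=bid, rid="r1", endpoint=endpoint, chambered=20)]
    return ctrl + treat


class TestApplyQC:
    @pytest.mark.parametrize(
        "dead,expected",
        [
            (2, QCStatus.accepted),               # 4%
            (5, QCStatus.accepted_with_correction),  # 10%
            (10, QCStatus.discarded),             # 20% boundary
            (13, QCStatus.discarded),             # 26%
        ],
    )
    def test_mortality_bands(self, dead, expected):
        ds = BioassayDataset(bioassay("a1", dead))
        _, reports = apply_qc(ds)
        assert reports[0].status == expected

    def test_exact_five_percent_left_uncorrected(self):
        ds = BioassayDataset(bioassay("a1", 1, n_ctrl=20))  # exactly 5%
        _, reports = apply_qc(ds)
        assert reports[0].status == QCStatus.accepted

    def test_oviposition_low_control_laying_discarded(self):
        # 38/50 not laying -> laying rate 24% < 30%
        ds = BioassayDataset(bioassay("o1", 38, endpoint=EndpointType.oviposition))
        _, reports = apply_qc(ds)
        assert reports[0].status == QCStatus.discarded
        ok = BioassayDataset(bioassay("o2", 30, endpoint=EndpointType.oviposition))
        _, reports = apply_qc(ok)
        assert reports[0].status == QCStatus.accepted

    def test_no_control_flagged_unevaluable(self):
        ds = BioassayDataset([rec(1.0, 25, 20)])
        accepted, reports = apply_qc(ds)
        assert reports[0].status == QCStatus.unevaluable
        assert len(accepted) == 0

    def test_partition_of_bioassays(self):
        ds = BioassayDataset(
            bioassay("a1", 2) + bioassay("a2", 6) + bioassay("a3", 20)
            + [rec(1.0, 25, 20, bid="a4")]
        )
        accepted, reports = apply_qc(ds)
        statuses = [r.status for r in reports]
        assert len(statuses) == 4
        accepted_ids = {r.bioassay_id for r in accepted}
        assert accepted_ids == {"a1", "a2"}
        assert statuses.count(QCStatus.discarded) == 1
        assert statuses.count(QCStatus.unevaluable) == 1


class TestAbbott:
    def test_formula(self):
        assert abbott_correct(0.6, 0.2) == pytest.approx(0.5)

    def test_identity_at_zero_control(self):
        assert abbott_correct(0.37, 0.0) == pytest.approx(0.37)

    def test_clamped_below(self):
        assert abbott_correct(0.1, 0.2) == 0.0

    def test_full_control_mortality_undefined(self):
        with pytest.raises(UndefinedCorrectionError):
            abbott_correct(0.5, 1.0)

    @given(
        p_control=st.floats(0, 0.99),
        p1=st.floats(0, 1),
        p2=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_observed_and_zero_at_control(self, p_control, p1, p2):
        lo, hi = sorted([p1, p2])
        assert abbott_correct(lo, p_control) <= abbott_correct(hi, p_control)
        assert abbott_correct(p_control, p_control) == 0.0


class TestOI:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [(0.2, 0.8, 75.0), (0.8, 0.8, 0.0), (0.0, 0.5, 100.0)],
    )
    def test_formula_and_limits(self, treated, control, expected):
        assert compute_oi(treated, control) == pytest.approx(expected)

    def test_zero_control_laying_undefined(self):
        with pytest.raises(UndefinedOIError):
            compute_oi(0.2, 0.0)

    def test_clamped_to_zero_when_treated_lay_more(self):
        assert compute_oi(0.9, 0.5) == 0.0
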