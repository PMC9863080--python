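"""Bioassay data model, CSV interchange, quality control and endpoint arithmetic.

One :class:`BioassayRecord` is a single exposure unit: the mosquitoes in one
bottle (replicate) at one insecticide concentration, with the count responding
at the recording time.  A bioassay is one concentration series run on one date
(``bioassay_id``); a campaign is a collection of bioassays across
institutions, species and insecticides, held in a :class:`BioassayDataset`.

Two endpoint families are supported:

* ``mortality`` — dead / exposed at 24 h or 72 h.
* ``oviposition`` — among surviving females individually chambered after the
  holding period (``n_chambered``), the number NOT laying eggs.

Quality control follows the WHO conventions: a mortality bioassay whose pooled
control mortality is >= 20% is discarded; between 5% and 20% (exclusive) the
bioassay is retained and corrected for background mortality (Abbott-analogous,
implemented in the curve model through its Z parameter); an oviposition
bioassay whose control laying rate falls below 30% is discarded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EndpointType",
    "QCStatus",
    "BioassayRecord",
    "BioassayDataset",
    "QCReport",
    "BioassayError",
    "BioassayFormatError",
    "BioassayValidationError",
    "EmptyDatasetError",
    "GroupingError",
    "UndefinedCorrectionError",
    "UndefinedOIError",
    "CSV_COLUMNS",
    "read_bioassay_csv",
    "write_bioassay_csv",
    "pool_replicates",
    "apply_qc",
    "abbott_correct",
    "compute_oi",
]


class BioassayError(Exception):
    """Base class for bioassay data errors."""


class BioassayFormatError(BioassayError):
    """Malformed file: missing column, unreadable header."""


class BioassayValidationError(BioassayError):
    """A record violates a count or concentration invariant."""


class EmptyDatasetError(BioassayError):
    """No records could be read."""


class GroupingError(BioassayError):
    """Records mixed across incompatible grouping keys."""


class UndefinedCorrectionError(BioassayError):
    """Abbott correction with 100% control response is undefined."""


class UndefinedOIError(BioassayError):
    """Oviposition inhibition with zero control laying is undefined."""


class EndpointType(str, enum.Enum):
    mortality = "mortality"
    oviposition = "oviposition"


class QCStatus(str, enum.Enum):
    accepted = "accepted"
    accepted_with_correction = "accepted_with_correction"
    discarded = "discarded"
    unevaluable = "unevaluable"


#: Canonical CSV header, in order.
CSV_COLUMNS = [
    "institution",
    "country",
    "species",
    "strain",
    "insecticide",
    "endpoint_type",
    "bioassay_id",
    "replicate_id",
    "concentration_ug_per_bottle",
    "n_exposed",
    "n_responded",
    "n_chambered",
    "recording_time_h",
]

#: Keys identifying one bioassay (a concentration series run once).
BIOASSAY_KEYS = ["institution", "species", "insecticide", "bioassay_id"]

#: Keys identifying one fitting scope (one curve per the pooled convention).
SCOPE_KEYS = ["institution", "species", "insecticide"]


@dataclass(frozen=True)
class BioassayRecord:
    """One bottle-replicate at one concentration.

    ``n_responded`` counts dead mosquitoes for mortality endpoints and
    non-ovipositing females among ``n_chambered`` survivors for oviposition
    endpoints.  ``concentration`` is in µg active ingredient per bottle; 0
    denotes the solvent/surfactant control.
    """

    institution: str
    country: str
    species: str
    strain: str
    insecticide: str
    endpoint_type: EndpointType
    bioassay_id: str
    replicate_id: str
    concentration: float
    n_exposed: int
    n_responded: int
    n_chambered: int | None = None
    recording_time_h: int = 24

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise BioassayValidationError(
                f"negative concentration {self.concentration!r}"
            )
        if self.n_exposed <= 0:
            raise BioassayValidationError(f"n_exposed must be positive, got {self.n_exposed}")
        if self.n_responded < 0:
            raise BioassayValidationError(f"negative n_responded {self.n_responded}")
        if self.endpoint_type == EndpointType.oviposition:
            if self.n_chambered is None:
                raise BioassayValidationError("oviposition record requires n_chambered")
            if self.n_chambered > self.n_exposed:
                raise BioassayValidationError(
                    f"n_chambered {self.n_chambered} > n_exposed {self.n_exposed}"
                )
            if self.n_responded > self.n_chambered:
                raise BioassayValidationError(
                    f"n_responded {self.n_responded} > n_chambered {self.n_chambered}"
                )
        elif self.n_responded > self.n_exposed:
            raise BioassayValidationError(
                f"n_responded {self.n_responded} > n_exposed {self.n_exposed}"
            )
        if self.recording_time_h <= 0:
            raise BioassayValidationError("recording_time_h must be positive")

    @property
    def is_control(self) -> bool:
        return self.concentration == 0.0

    @property
    def denominator(self) -> int:
        """Trial count for the binomial outcome (chambered for oviposition)."""
        if self.endpoint_type == EndpointType.oviposition:
            assert self.n_chambered is not None
            return self.n_chambered
        return self.n_exposed


@dataclass
class BioassayDataset:
    """Ordered collection of records with free-text provenance."""

    records: list[BioassayRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "institution": r.institution,
                    "country": r.country,
                    "species": r.species,
                    "strain": r.strain,
                    "insecticide": r.insecticide,
                    "endpoint_type": r.endpoint_type.value,
                    "bioassay_id": r.bioassay_id,
                    "replicate_id": r.replicate_id,
                    "concentration_ug_per_bottle": r.concentration,
                    "n_exposed": r.n_exposed,
                    "n_responded": r.n_responded,
                    "n_chambered": r.n_chambered,
                    "recording_time_h": r.recording_time_h,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def groupby_bioassay(self) -> dict[tuple, list[BioassayRecord]]:
        groups: dict[tuple, list[BioassayRecord]] = {}
        for r in self.records:
            key = (r.institution, r.species, r.insecticide, r.bioassay_id)
            groups.setdefault(key, []).append(r)
        return groups

    def groupby_scope(self) -> dict[tuple, list[BioassayRecord]]:
        groups: dict[tuple, list[BioassayRecord]] = {}
        for r in self.records:
            key = (r.institution, r.species, r.insecticide)
            groups.setdefault(key, []).append(r)
        return groups

    def filter(self, **labels: str) -> "BioassayDataset":
        """Subset by equality on any record label field."""
        kept = [
            r
            for r in self.records
            if all(getattr(r, k) == v for k, v in labels.items())
        ]
        return BioassayDataset(kept, provenance=self.provenance)


def _parse_row(row: pd.Series, row_number: int) -> BioassayRecord:
    try:
        endpoint = EndpointType(str(row["endpoint_type"]).strip())
    except ValueError as exc:
        raise BioassayValidationError(
            f"row {row_number}: unknown endpoint_type {row['endpoint_type']!r}"
        ) from exc
    raw_chambered = row["n_chambered"]
    chambered: int | None
    if raw_chambered is None or (isinstance(raw_chambered, float) and math.isnan(raw_chambered)) or raw_chambered == "":
        chambered = None
    else:
        chambered = int(raw_chambered)
    try:
        return BioassayRecord(
            institution=str(row["institution"]),
            country=str(row["country"]),
            species=str(row["species"]),
            strain=str(row["strain"]),
            insecticide=str(row["insecticide"]),
            endpoint_type=endpoint,
            bioassay_id=str(row["bioassay_id"]),
            replicate_id=str(row["replicate_id"]),
            concentration=float(row["concentration_ug_per_bottle"]),
            n_exposed=int(row["n_exposed"]),
            n_responded=int(row["n_responded"]),
            n_chambered=chambered,
            recording_time_h=int(row["recording_time_h"]),
        )
    except BioassayValidationError as exc:
        raise BioassayValidationError(f"row {row_number}: {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise BioassayValidationError(f"row {row_number}: unparseable value ({exc})") from exc


def read_bioassay_csv(path: str | Path) -> BioassayDataset:
    """Read the canonical bioassay CSV.

    Raises :class:`BioassayFormatError` when a required column is missing,
    :class:`BioassayValidationError` (with the offending row number, counting
    the header as row 1) when a record violates an invariant, and
    :class:`EmptyDatasetError` for a file with no data rows.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", dtype={"bioassay_id": str, "replicate_id": str})
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"{path} contains no data") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise BioassayFormatError(f"{path} is missing required column(s): {', '.join(missing)}")
    if frame.empty:
        raise EmptyDatasetError(f"{path} has a header but no records")
    records = [
        _parse_row(row, row_number=i + 2)  # header is row 1
        for i, (_, row) in enumerate(frame.iterrows())
    ]
    return BioassayDataset(records, provenance=str(path))


def write_bioassay_csv(ds: BioassayDataset, path: str | Path, header_comment: str | None = None) -> None:
    """Write the canonical CSV; concentrations keep 12 significant digits."""
    path = Path(path)
    frame = ds.to_frame().copy()
    frame["concentration_ug_per_bottle"] = frame["concentration_ug_per_bottle"].map(
        lambda v: format(v, ".12g")
    )
    frame["n_chambered"] = frame["n_chambered"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(int(v))
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def pool_replicates(group: Sequence[BioassayRecord]) -> tuple[int, int]:
    """Pool replicate counts at one concentration of one bioassay.

    Returns ``(n_total, y_total)``: the summed binomial denominator (exposed
    for mortality, chambered for oviposition) and the summed responders.
    """
    if not group:
        raise GroupingError("empty replicate group")
    endpoint_types = {r.endpoint_type for r in group}
    if len(endpoint_types) > 1:
        raise GroupingError(f"mixed endpoint types in one group: {endpoint_types}")
    keys = {(r.bioassay_id, r.concentration) for r in group}
    if len(keys) > 1:
        raise GroupingError(f"records from multiple (bioassay, concentration) cells: {keys}")
    n_total = sum(r.denominator for r in group)
    y_total = sum(r.n_responded for r in group)
    return n_total, y_total


def abbott_correct(p_obs: float, p_control: float) -> float:
    """Abbott's correction for background control response.

    ``(p_obs - p_control) / (1 - p_control)``, clamped to [0, 1].  Reporting
    convenience only: in model fits the correction is absorbed by the curve's
    background parameter Z.
    """
    if not (0.0 <= p_obs <= 1.0):
        raise ValueError(f"p_obs out of [0,1]: {p_obs}")
    if not (0.0 <= p_control <= 1.0):
        raise ValueError(f"p_control out of [0,1]: {p_control}")
    if p_control == 1.0:
        raise UndefinedCorrectionError("control response of 100% leaves no signal to correct")
    corrected = (p_obs - p_control) / (1.0 - p_control)
    return min(1.0, max(0.0, corrected))


def compute_oi(treated_laying_prop: float, control_laying_prop: float) -> float:
    """Oviposition-inhibition percentage relative to the control laying rate.

    ``OI% = 100 * (1 - treated/control)``, clamped to [0, 100].
    """
    if control_laying_prop == 0.0:
        raise UndefinedOIError("control laying rate of zero makes OI undefined")
    if not (0.0 < control_laying_prop <= 1.0):
        raise ValueError(f"control_laying_prop out of (0,1]: {control_laying_prop}")
    if not (0.0 <= treated_laying_prop <= 1.0):
        raise ValueError(f"treated_laying_prop out of [0,1]: {treated_laying_prop}")
    oi = 100.0 * (1.0 - treated_laying_prop / control_laying_prop)
    return min(100.0, max(0.0, oi))


@dataclass(frozen=True)
class QCReport:
    """Per-bioassay quality-control verdict."""

    institution: str
    species: str
    insecticide: str
    bioassay_id: str
    endpoint_type: EndpointType
    status: QCStatus
    reason: str
    control_response_rate: float | None

    def to_dict(self) -> dict:
        return {
            "institution": self.institution,
            "species": self.species,
            "insecticide": self.insecticide,
            "bioassay_id": self.bioassay_id,
            "endpoint_type": self.endpoint_type.value,
            "status": self.status.value,
            "reason": self.reason,
            "control_response_rate": self.control_response_rate,
        }


def _pool_controls(records: Iterable[BioassayRecord]) -> tuple[int, int]:
    controls = [r for r in records if r.is_control]
    n = sum(r.denominator for r in controls)
    y = sum(r.n_responded for r in controls)
    return n, y


def apply_qc(
    ds: BioassayDataset,
    mortality_discard: float = 0.20,
    correction_floor: float = 0.05,
    oviposition_floor: float = 0.30,
) -> tuple[BioassayDataset, list[QCReport]]:
    """Screen every bioassay against the control-response rules.

    Mortality bioassays: pooled control mortality >= ``mortality_discard`` is
    discarded; strictly between ``correction_floor`` and ``mortality_discard``
    is accepted with background correction (applied in the model via Z); at or
    below the floor, accepted as-is.  A control mortality of exactly the floor
    is left uncorrected; the boundary choice is noted in the report reason.

    Oviposition bioassays: a pooled control laying rate (1 minus the control
    non-laying proportion) below ``oviposition_floor`` is discarded.

    Bioassays without any control replicate are flagged unevaluable and
    excluded from the accepted dataset.
    """
    reports: list[QCReport] = []
    accepted_records: list[BioassayRecord] = []
    for (institution, species, insecticide, bioassay_id), group in ds.groupby_bioassay().items():
        endpoint = group[0].endpoint_type
        n_ctrl, y_ctrl = _pool_controls(group)
        if n_ctrl == 0:
            reports.append(
                QCReport(
                    institution, species, insecticide, bioassay_id, endpoint,
                    QCStatus.unevaluable, "no control replicates", None,
                )
            )
            continue
        rate = y_ctrl / n_ctrl
        if endpoint == EndpointType.mortality:
            if rate >= mortality_discard:
                status, reason = QCStatus.discarded, (
                    f"control mortality {rate:.1%} >= {mortality_discard:.0%}"
                )
            elif rate > correction_floor:
                status, reason = QCStatus.accepted_with_correction, (
                    f"control mortality {rate:.1%} in ({correction_floor:.0%}, "
                    f"{mortality_discard:.0%}); corrected via model background Z"
                )
            else:
                status, reason = QCStatus.accepted, (
                    f"control mortality {rate:.1%} <= {correction_floor:.0%}"
                )
        else:
            laying_rate = 1.0 - rate
            if laying_rate < oviposition_floor:
                status, reason = QCStatus.discarded, (
                    f"control laying rate {laying_rate:.1%} < {oviposition_floor:.0%}"
                )
            else:
                status, reason = QCStatus.accepted, (
                    f"control laying rate {laying_rate:.1%} >= {oviposition_floor:.0%}"
                )
        reports.append(
            QCReport(institution, species, insecticide, bioassay_id, endpoint, status, reason, rate)
        )
        if status in (QCStatus.accepted, QCStatus.accepted_with_correction):
            accepted_records.extend(group)
    accepted = BioassayDataset(
        [r for r in ds.records if r in set(accepted_records)], provenance=ds.provenance
    )
    return accepted, reports


def qc_report_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])
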