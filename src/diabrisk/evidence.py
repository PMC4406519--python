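"""Literature-derived evidence tables and their conversion to dose-response datasets.

Clinical trials report factor/complication relationships as "from-to" records:
when the factor moved from one value to another, the complication risk moved
from one percentage to another. Each record is three-dimensional as published
(interval x interval) but is consumed downstream as two two-dimensional points,
one per endpoint, so that a curve can be fitted through the scatter.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FromToRecord",
    "RiskPoint",
    "DoseResponseDataset",
    "records_to_points",
    "mean_arterial_pressure",
    "scale_by_anchor",
]

RELATION_TYPES = ("cause", "prevents", "same")

#: Column layout of an evidence CSV (one FromToRecord per row).
EVIDENCE_COLUMNS = (
    "factor",
    "complication",
    "relation",
    "factor_from",
    "factor_to",
    "risk_from",
    "risk_to",
    "source",
)


@dataclass(frozen=True)
class FromToRecord:
    """One literature finding: factor moved from->to, risk moved from->to.

    ``relation_type`` is ``"cause"`` (factor increases risk), ``"prevents"``
    (factor decreases risk) or ``"same"`` (two names for one condition).
    "prevents" records are stored untransformed: a downward slope in the data
    is the fitted curve's job to capture, risks are never negated.
    """

    factor_name: str
    complication_name: str
    relation_type: str
    factor_from: float
    factor_to: float
    risk_from: float
    risk_to: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.relation_type not in RELATION_TYPES:
            raise ValueError(
                f"relation_type must be one of {RELATION_TYPES}, got {self.relation_type!r}"
            )
        if self.risk_from < 0 or self.risk_to < 0:
            raise ValueError("risk percentages must be non-negative")
        if self.factor_from == self.factor_to:
            raise ValueError("factor_from and factor_to must differ")
        for r in (self.risk_from, self.risk_to):
            if r > 100:
                warnings.warn(
                    f"risk percentage {r} exceeds 100 (rates per 100 patient-years "
                    "can exceed 100%); kept as-is",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class RiskPoint:
    """A single (factor value, risk percent) observation."""

    factor_value: float
    risk_percent: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor_value) or not np.isfinite(self.risk_percent):
            raise ValueError("RiskPoint fields must be finite")
        if self.risk_percent < 0:
            raise ValueError("risk_percent must be non-negative")


@dataclass(frozen=True)
class DoseResponseDataset:
    """Ordered (factor value, risk percent) pairs for one factor-complication pair.

    Points are stored sorted ascending by factor value; duplicate factor values
    from distinct sources are retained (all findings carry the same weight).
    """

    factor_name: str
    complication_name: str
    points: tuple[RiskPoint, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.points, key=lambda p: (p.factor_value, p.risk_percent))
        )
        object.__setattr__(self, "points", ordered)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        """Factor values, ascending."""
        return np.array([p.factor_value for p in self.points], dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Risk percentages, aligned with :attr:`x`."""
        return np.array([p.risk_percent for p in self.points], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"factor_value": self.x, "risk_percent": self.y})

    def to_csv(self, path: str | Path | io.IOBase) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path | io.IOBase,
        factor_name: str = "",
        complication_name: str = "",
    ) -> "DoseResponseDataset":
        df = pd.read_csv(path)
        missing = {"factor_value", "risk_percent"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV lacks required columns: {sorted(missing)}")
        pts = tuple(
            RiskPoint(float(r.factor_value), float(r.risk_percent))
            for r in df.itertuples()
        )
        return cls(factor_name, complication_name, pts)


def records_to_points(records: Sequence[FromToRecord]) -> DoseResponseDataset:
    """Flatten from-to records into a two-dimensional dose-response dataset.

    Each record contributes its two endpoints as separate points; no
    interpolation between them is performed. All records must describe the
    same factor-complication pair.
    """
    if not records:
        raise ValueError("cannot build a dataset from an empty record list")
    pair = (records[0].factor_name, records[0].complication_name)
    for rec in records:
        other = (rec.factor_name, rec.complication_name)
        if other != pair:
            raise ValueError(
                f"records mix factor/complication pairs: {pair} vs {other}"
            )
    pts = []
    for rec in records:
        pts.append(RiskPoint(rec.factor_from, rec.risk_from))
        pts.append(RiskPoint(rec.factor_to, rec.risk_to))
    return DoseResponseDataset(pair[0], pair[1], tuple(pts))


def read_evidence_csv(path: str | Path | io.IOBase) -> list[FromToRecord]:
    """Read an evidence CSV (header ``factor,complication,relation,...``)."""
    df = pd.read_csv(path)
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence CSV lacks required columns: {sorted(missing)}")
    return [
        FromToRecord(
            factor_name=str(r.factor),
            complication_name=str(r.complication),
            relation_type=str(r.relation),
            factor_from=float(r.factor_from),
            factor_to=float(r.factor_to),
            risk_from=float(r.risk_from),
            risk_to=float(r.risk_to),
            source_id=str(r.source),
        )
        for r in df.itertuples()
    ]


def mean_arterial_pressure(systolic: float, diastolic: float) -> float:
    """Mean arterial pressure, MAP = DP + (SP - DP)/3, in mmHg.

    The standard single-scalar summary of blood pressure: diastole occupies
    roughly two thirds of the cardiac cycle, so the diastolic pressure gets
    twice the weight of the systolic.
    """
    if diastolic <= 0:
        raise ValueError("diastolic pressure must be positive")
    if systolic < diastolic:
        raise ValueError(
            f"systolic ({systolic}) must be >= diastolic ({diastolic})"
        )
    return diastolic + (systolic - diastolic) / 3.0


def scale_by_anchor(
    anchor_risk: float, relative_factors: Iterable[float]
) -> list[float]:
    """Convert relative risk changes to absolute percentages via one anchor.

    Studies often report only the fold-change in risk along a factor's range;
    given the absolute risk of the first point (the anchor), the remaining
    absolute risks are the anchor times each multiplicative change factor.
    """
    if anchor_risk <= 0:
        raise ValueError("anchor risk must be positive")
    return [anchor_risk * f for f in relative_factors]
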