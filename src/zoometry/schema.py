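"""Measurement schema and per-animal records.

An :class:`AnimalRecord` bundles one animal's identity (biotype, sex),
optional live weight (kg) and its linear body measurements (cm) keyed by
the 17 standard zoometric codes (``HL`` head length ... ``NL`` neck
length; see :data:`zoometry.calibration.MEASUREMENT_NAMES`).

Validation distinguishes *hard* failures (non-positive or non-finite
values, which make a record unusable) from *soft* plausibility warnings
(a value far outside the calibrated range for its trait, which merely
flags a likely recording error).  Records are never mutated by
validation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import calibration


class Biotype(enum.Enum):
    """Creole cattle biotype (within-breed phenotypic variant)."""

    NEGRO = "NEGRO"
    CALLEJON = "CALLEJON"
    ATIGRADO = "ATIGRADO"


class Sex(enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"


class SchemaError(ValueError):
    """Input does not conform to the record schema."""


class MeasurementError(ValueError):
    """A measurement value violates a hard invariant."""


@dataclass(frozen=True)
class AnimalRecord:
    """One animal: identity, optional live weight, named measurements.

    Parameters
    ----------
    animal_id : opaque identifier, never interpreted.
    biotype, sex : population strata.
    measurements : mapping from measurement code to length in cm.
        Unknown codes are rejected; values must be positive and finite.
    live_weight : optional live weight in kg.
    annotations : passthrough of unrecognised input columns.
    """

    animal_id: str
    biotype: Biotype
    sex: Sex
    measurements: Mapping[str, float] = field(default_factory=dict)
    live_weight: float | None = None
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.measurements) - set(calibration.MEASUREMENTS)
        if unknown:
            raise SchemaError(
                f"unknown measurement codes: {sorted(unknown)}"
            )
        for code, value in self.measurements.items():
            if not math.isfinite(value):
                raise MeasurementError(
                    f"non-finite measurement {code}={value!r} "
                    f"(animal {self.animal_id})"
                )
            if value <= 0:
                raise MeasurementError(
                    f"non-positive measurement {code}={value!r} "
                    f"(animal {self.animal_id})"
                )
        if self.live_weight is not None and not (
            math.isfinite(self.live_weight) and self.live_weight > 0
        ):
            raise MeasurementError(
                f"invalid live weight {self.live_weight!r} "
                f"(animal {self.animal_id})"
            )

    @property
    def missing(self) -> frozenset[str]:
        """Measurement codes absent from this record."""
        return frozenset(calibration.MEASUREMENTS) - set(self.measurements)

    @property
    def complete(self) -> bool:
        """True when all 17 measurements are present."""
        return not self.missing

    def scaled(self, factor: float) -> "AnimalRecord":
        """Return a copy with every length multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return AnimalRecord(
            animal_id=self.animal_id,
            biotype=self.biotype,
            sex=self.sex,
            measurements={k: v * factor for k, v in self.measurements.items()},
            live_weight=self.live_weight,
            annotations=self.annotations,
        )


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of plausibility screening for one record."""

    animal_id: str
    hard_failures: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.hard_failures


def validate_record(
    record: AnimalRecord,
    *,
    reference_means: Mapping[str, float] | None = None,
    reference_cv: Mapping[str, float] | None = None,
    n_sd: float = 5.0,
) -> ValidationReport:
    """Screen a record for implausible values.

    Hard failures cannot occur for a constructed :class:`AnimalRecord`
    (the constructor enforces positivity/finiteness) but are reported for
    raw mappings passed through :func:`validate_values`.  Soft warnings
    flag measurements outside ``mean +/- n_sd * SD`` of the calibration,
    where SD is derived from the calibrated CV%.  Screening is advisory:
    the record is returned unchanged and the pipeline proceeds.
    """
    means = reference_means or calibration.REFERENCE_POOLED_MEANS
    cvs = reference_cv or calibration.REFERENCE_TRAIT_CV
    warnings: list[str] = []
    for code, value in sorted(record.measurements.items()):
        if code not in means or code not in cvs:
            continue
        mean = means[code]
        sd = cvs[code] / 100.0 * mean
        lo, hi = mean - n_sd * sd, mean + n_sd * sd
        if not (lo <= value <= hi):
            warnings.append(
                f"{code}={value:g} outside plausible range "
                f"[{lo:.2f}, {hi:.2f}] (mean {mean:g} +/- {n_sd:g} SD)"
            )
    return ValidationReport(
        animal_id=record.animal_id,
        hard_failures=(),
        warnings=tuple(warnings),
    )


def validate_values(
    animal_id: str, values: Mapping[str, float]
) -> ValidationReport:
    """Hard-screen a raw code->value mapping before record construction."""
    failures = []
    for code, value in sorted(values.items()):
        if not math.isfinite(value):
            failures.append(f"{code}={value!r}: non-finite measurement")
        elif value <= 0:
            failures.append(f"{code}={value!r}: non-positive measurement")
    return ValidationReport(
        animal_id=animal_id,
        hard_failures=tuple(failures),
        warnings=(),
    )


def complete_records(records: Iterable[AnimalRecord]) -> list[AnimalRecord]:
    """The subset of records carrying all 17 measurements."""
    return [r for r in records if r.complete]
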