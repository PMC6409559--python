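"""Breath-by-breath VO2 series container.

A :class:`BreathSeries` is an immutable (time, VO2) signal with units,
provenance and an append-only edit log.  Time is in seconds from exercise
onset; VO2 is either normalized to body mass (mL·kg⁻¹·min⁻¹, the canonical
internal unit) or absolute (mL·min⁻¹, convertible given body mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from .errors import EmptySeriesError, InvalidInputError

PER_KG = "per_kg"
ABSOLUTE = "absolute"


@dataclass(frozen=True)
class EditRecord:
    """One entry of the replayable edit log."""

    op: str
    params: Mapping[str, Any]
    indices_removed: tuple[int, ...] | None = None


@dataclass(frozen=True)
class BreathSeries:
    time: np.ndarray
    vo2: np.ndarray
    unit: str = PER_KG
    body_mass: float | None = None
    label: str = ""
    edits: tuple[EditRecord, ...] = field(default_factory=tuple)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.vo2, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "vo2", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise InvalidInputError("time and vo2 must be 1-d arrays of equal length")
        if t.size == 0:
            raise EmptySeriesError("series has no samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise InvalidInputError("time and vo2 must be finite")
        if np.any(v < 0):
            raise InvalidInputError("vo2 values must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(
                "time must be strictly increasing (resolve duplicates with from_samples)"
            )
        if self.unit not in (PER_KG, ABSOLUTE):
            raise InvalidInputError(f"unknown unit {self.unit!r}")
        t.setflags(write=False)
        v.setflags(write=False)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_samples(
        cls,
        time,
        vo2,
        unit: str = PER_KG,
        body_mass: float | None = None,
        label: str = "",
    ) -> "BreathSeries":
        """Build a series from raw samples: sort by time and average
        duplicate timestamps into one sample before invariant checks."""
        t = np.asarray(time, dtype=float)
        v = np.asarray(vo2, dtype=float)
        if t.size == 0:
            raise EmptySeriesError("no samples provided")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise InvalidInputError("time and vo2 must be finite")
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        uniq, inverse = np.unique(t, return_inverse=True)
        if uniq.size != t.size:
            sums = np.bincount(inverse, weights=v)
            counts = np.bincount(inverse)
            t, v = uniq, sums / counts
        return cls(t, v, unit=unit, body_mass=body_mass, label=label)

    # -- basic properties ---------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def t_start(self) -> float:
        return float(self.time[0])

    @property
    def t_end(self) -> float:
        return float(self.time[-1])

    @property
    def span(self) -> float:
        return self.t_end - self.t_start

    # -- derived series -----------------------------------------------------

    def to_per_kg(self) -> "BreathSeries":
        """Convert absolute VO2 (mL·min⁻¹) to mL·kg⁻¹·min⁻¹ using body mass."""
        if self.unit == PER_KG:
            return self
        if self.body_mass is None or self.body_mass <= 0:
            raise InvalidInputError(
                "body_mass (kg) is required to convert absolute VO2 to per-kg"
            )
        rec = EditRecord("to_per_kg", {"body_mass": self.body_mass})
        return replace(
            self,
            vo2=self.vo2 / self.body_mass,
            unit=PER_KG,
            edits=self.edits + (rec,),
        )

    def with_samples(
        self, time: np.ndarray, vo2: np.ndarray, edit: EditRecord
    ) -> "BreathSeries":
        """New series with the same metadata, new samples and a logged edit."""
        if np.asarray(time).size == 0:
            raise EmptySeriesError(f"operation {edit.op!r} removed all samples")
        return replace(self, time=np.asarray(time, float), vo2=np.asarray(vo2, float),
                       edits=self.edits + (edit,))
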