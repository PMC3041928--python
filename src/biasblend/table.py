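"""Core data model for multi-source small-area prevalence estimates.

An :class:`EstimateTable` holds one point estimate (in percent) and one
sampling standard error (in percentage points) per (area, source) cell,
together with a presence mask for cells that no source reported.  The
sampling standard errors are treated as known throughout the package:
providers publish 95% confidence intervals, and the SE is recovered by
dividing the interval width by 3.92 (the width of a symmetric 95% normal
interval in SE units).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: width of a symmetric 95% Wald interval, in units of the standard error
WALD_95_WIDTH = 3.92

#: percentage points of asymmetry before a CI is flagged as non-Wald
CI_ASYMMETRY_TOL = 0.1


class DataValidationError(ValueError):
    """An estimate table violates a structural invariant."""


class DegenerateIntervalError(ValueError):
    """A confidence interval has non-positive width."""


class DataWarning(UserWarning):
    """Non-fatal data issue (SE/CI disagreement, asymmetric interval, ...)."""


def se_from_interval(lower, upper):
    """Standard error implied by a symmetric 95% confidence interval.

    Parameters
    ----------
    lower, upper : float or array-like
        Interval endpoints in percent, ``upper > lower`` elementwise.

    Returns
    -------
    float or ndarray
        ``(upper - lower) / 3.92`` in percentage points.
    """
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if np.any(hi <= lo):
        raise DegenerateIntervalError(
            "confidence interval must have upper > lower (zero-width or "
            "inverted interval supplied)"
        )
    out = (hi - lo) / WALD_95_WIDTH
    if np.isscalar(lower) and np.isscalar(upper):
        return float(out)
    return out


@dataclass
class EstimateTable:
    """Rectangular grid of prevalence estimates from several sources.

    Attributes
    ----------
    area_labels : list of str
        The A small-area names (rows).
    source_labels : list of str
        The S data-source names (columns).
    y : (A, S) ndarray
        Prevalence point estimates in percent.  Values in non-present
        cells are ignored (conventionally NaN).
    se : (A, S) ndarray
        Known sampling standard deviations in percentage points.
    present : (A, S) bool ndarray
        Mask of available cells.
    source_year : (S,) int ndarray, optional
        Mid-survey calendar year per source; required only for the
        time-trend model.
    adjusted : bool
        True when the table holds bias-adjusted rather than raw estimates.
    """

    area_labels: list
    source_labels: list
    y: np.ndarray
    se: np.ndarray
    present: np.ndarray = None
    source_year: np.ndarray = None
    adjusted: bool = False

    def __post_init__(self):
        self.area_labels = [str(a) for a in self.area_labels]
        self.source_labels = [str(s) for s in self.source_labels]
        self.y = np.array(self.y, dtype=float)
        self.se = np.array(self.se, dtype=float)
        A, S = len(self.area_labels), len(self.source_labels)
        if self.y.shape != (A, S) or self.se.shape != (A, S):
            raise DataValidationError(
                f"y/se must have shape ({A}, {S}); got {self.y.shape} and "
                f"{self.se.shape}"
            )
        if self.present is None:
            self.present = np.ones((A, S), dtype=bool)
        else:
            self.present = np.array(self.present, dtype=bool)
            if self.present.shape != (A, S):
                raise DataValidationError("present mask has wrong shape")
        if self.source_year is not None:
            self.source_year = np.array(self.source_year, dtype=int)
            if self.source_year.shape != (S,):
                raise DataValidationError("source_year must have one entry per source")

    # -- basic geometry -------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.area_labels)

    @property
    def n_sources(self) -> int:
        return len(self.source_labels)

    @property
    def se2(self) -> np.ndarray:
        """Known sampling variances (percentage points squared)."""
        return self.se ** 2

    def copy(self) -> "EstimateTable":
        return EstimateTable(
            list(self.area_labels),
            list(self.source_labels),
            self.y.copy(),
            self.se.copy(),
            self.present.copy(),
            None if self.source_year is None else self.source_year.copy(),
            self.adjusted,
        )

    def fingerprint(self) -> str:
        """Stable content hash used to match fits to their input table."""
        h = hashlib.sha1()
        h.update("|".join(self.area_labels).encode())
        h.update("|".join(self.source_labels).encode())
        y = np.where(self.present, self.y, 0.0)
        se = np.where(self.present, self.se, 0.0)
        h.update(np.ascontiguousarray(y).tobytes())
        h.update(np.ascontiguousarray(se).tobytes())
        h.update(np.ascontiguousarray(self.present).tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        """Long-form DataFrame with one row per present cell."""
        rows = []
        for i, a in enumerate(self.area_labels):
            for j, s in enumerate(self.source_labels):
                if not self.present[i, j]:
                    continue
                row = {"area": a, "source": s}
                if self.source_year is not None:
                    row["year"] = int(self.source_year[j])
                row["estimate"] = self.y[i, j]
                row["se"] = self.se[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`.

    ``issues`` is a list of ``(severity, locator, message)`` triples where
    severity is ``"warning"`` or ``"error"`` and the locator names a cell
    (``"area/source"``), a row/column (``"area:X"``, ``"source:Y"``) or the
    whole table (``"table"``).
    """

    issues: list = field(default_factory=list)

    def add(self, severity: str, locator: str, message: str) -> None:
        self.issues.append((severity, locator, message))

    @property
    def errors(self) -> list:
        return [i for i in self.issues if i[0] == "error"]

    @property
    def warnings(self) -> list:
        return [i for i in self.issues if i[0] == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_for_errors(self) -> None:
        if self.errors:
            lines = [f"{loc}: {msg}" for _, loc, msg in self.errors]
            raise DataValidationError(
                "estimate table failed validation:\n  " + "\n  ".join(lines)
            )


def validate_table(table: EstimateTable) -> ValidationReport:
    """Check every structural invariant of an :class:`EstimateTable`.

    Severity ``error`` blocks model fitting; ``warning`` does not.
    """
    rep = ValidationReport()
    A, S = table.n_areas, table.n_sources
    if len(set(table.area_labels)) != A:
        rep.add("error", "table", "duplicate area labels")
    if len(set(table.source_labels)) != S:
        rep.add("error", "table", "duplicate source labels")
    if A < 2:
        rep.add("error", "table", f"need at least 2 areas for any model fit (got {A})")
    if S < 2:
        rep.add("error", "table", f"need at least 2 sources for any model fit (got {S})")
    for i, a in enumerate(table.area_labels):
        for j, s in enumerate(table.source_labels):
            if not table.present[i, j]:
                continue
            loc = f"{a}/{s}"
            yij, seij = table.y[i, j], table.se[i, j]
            if not np.isfinite(yij) or not (0.0 < yij < 100.0):
                rep.add("error", loc, f"estimate {yij!r} not strictly inside (0, 100)")
            if not np.isfinite(seij) or not seij > 0.0:
                rep.add("error", loc, f"standard error {seij!r} not strictly positive")
    area_counts = table.present.sum(axis=1)
    src_counts = table.present.sum(axis=0)
    for i, a in enumerate(table.area_labels):
        if area_counts[i] < 1:
            rep.add("error", f"area:{a}", "area has no present cells")
    for j, s in enumerate(table.source_labels):
        if src_counts[j] < 2:
            rep.add(
                "error",
                f"source:{s}",
                "source has fewer than 2 present cells: "
                "bias variance unidentifiable",
            )
    return rep
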