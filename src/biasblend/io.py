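"""Reading and writing the long-form CSV interchange format.

The dialect is one row per present (area, source) cell with header
``area,source,year,estimate,se,ci_lower,ci_upper``; ``year`` and either
``se`` or the CI pair are optional per row.  When both ``se`` and a CI are
given, the ``se`` column wins; a disagreement beyond 1e-6 raises a
:class:`~biasblend.table.DataWarning`.  Lines starting with ``#`` are
provenance comments and are skipped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .table import (
    CI_ASYMMETRY_TOL,
    DataValidationError,
    DataWarning,
    EstimateTable,
    ValidationReport,
    se_from_interval,
    validate_table,
)

_MANDATORY = ("area", "source", "estimate")


def read_estimates(path, with_report: bool = False):
    """Read an :class:`EstimateTable` from a long-form CSV file.

    Parameters
    ----------
    path : str or Path
        CSV file in the documented dialect.
    with_report : bool
        When True, also return the :class:`ValidationReport` collecting
        data warnings (SE/CI disagreement, asymmetric intervals) alongside
        structural validation results.

    Raises
    ------
    DataValidationError
        On missing mandatory columns, duplicate (area, source) rows, rows
        giving neither an SE nor a complete CI, or any table-level
        validation error.
    """
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing mandatory columns: {missing}")

    report = ValidationReport()
    dup = df.duplicated(subset=["area", "source"], keep=False)
    if dup.any():
        pairs = sorted(
            {(r.area, r.source) for r in df.loc[dup].itertuples()}
        )
        raise DataValidationError(f"duplicate (area, source) rows: {pairs}")

    area_labels = list(dict.fromkeys(df["area"].astype(str)))
    source_labels = list(dict.fromkeys(df["source"].astype(str)))
    A, S = len(area_labels), len(source_labels)
    a_idx = {a: i for i, a in enumerate(area_labels)}
    s_idx = {s: j for j, s in enumerate(source_labels)}

    y = np.full((A, S), np.nan)
    se = np.full((A, S), np.nan)
    present = np.zeros((A, S), dtype=bool)
    years = {}

    has_se = "se" in df.columns
    has_ci = "ci_lower" in df.columns and "ci_upper" in df.columns
    for row in df.itertuples():
        i, j = a_idx[str(row.area)], s_idx[str(row.source)]
        loc = f"{row.area}/{row.source}"
        est = float(row.estimate)
        se_val = float(row.se) if has_se and pd.notna(row.se) else None
        ci = None
        if has_ci and pd.notna(row.ci_lower) and pd.notna(row.ci_upper):
            ci = (float(row.ci_lower), float(row.ci_upper))
        if se_val is None and ci is None:
            raise DataValidationError(
                f"{loc}: row gives neither 'se' nor a complete CI"
            )
        if ci is not None:
            ci_se = se_from_interval(*ci)
            asym = abs((ci[1] - est) - (est - ci[0]))
            if asym > CI_ASYMMETRY_TOL:
                msg = (
                    f"confidence interval asymmetric around the estimate by "
                    f"{asym:.3f} percentage points; Wald width/3.92 applied anyway"
                )
                report.add("warning", loc, msg)
                warnings.warn(f"{loc}: {msg}", DataWarning, stacklevel=2)
        if se_val is not None:
            if ci is not None and abs(se_val - ci_se) > 1e-6:
                msg = (
                    f"stated se {se_val:.6g} disagrees with CI-implied se "
                    f"{ci_se:.6g}; 'se' column takes precedence"
                )
                report.add("warning", loc, msg)
                warnings.warn(f"{loc}: {msg}", DataWarning, stacklevel=2)
            cell_se = se_val
        else:
            cell_se = ci_se
        y[i, j] = est
        se[i, j] = cell_se
        present[i, j] = True
        if "year" in df.columns and pd.notna(getattr(row, "year", None)):
            yr = int(row.year)
            if j in years and years[j] != yr:
                raise DataValidationError(
                    f"source {row.source} has conflicting years "
                    f"{years[j]} and {yr}"
                )
            years[j] = yr

    source_year = None
    if len(years) == S:
        source_year = np.array([years[j] for j in range(S)], dtype=int)
    elif years:
        report.add(
            "warning",
            "table",
            "year given for some but not all sources; years ignored",
        )

    table = EstimateTable(area_labels, source_labels, y, se, present, source_year)
    struct = validate_table(table)
    report.issues.extend(struct.issues)
    struct.raise_for_errors()
    if with_report:
        return table, report
    return table


def write_estimates(table: EstimateTable, path, header_lines=None) -> None:
    """Write an :class:`EstimateTable` as long-form CSV (present cells only).

    ``header_lines`` are emitted as leading ``#`` provenance comments.
    Round-trips through :func:`read_estimates` up to float formatting
    (full ``repr`` precision is used, so in practice exactly).
    """
    validate_table(table).raise_for_errors()
    df = table.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
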