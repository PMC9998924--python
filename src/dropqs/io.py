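"""Validated CSV input/output.

All tables are plain UTF-8 CSV. Files written by this package carry a
leading ``#`` comment line stating the units of each column, because the
pipeline mixes pg, pg/mL and per-10^5-cell scales; readers skip comment
lines. ``validate_csv`` checks a file against a named schema (required
columns, types, and monotonicity where the schema demands it) and returns a
list of human-readable violations — empty means the file is well-formed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DropqsError

__all__ = ["SCHEMAS", "read_table", "write_table", "validate_csv", "validate_frame"]

#: schema name -> (required columns, numeric columns, units comment)
SCHEMAS = {
    "standards": (
        ["cytokine", "concentration_pg_ml", "mfi"],
        ["concentration_pg_ml", "mfi"],
        "# units: concentration_pg_ml [pg/mL], mfi [a.u.]",
    ),
    "events": (
        ["cell_id", "donor", "condition", "tnfa_signal", "il10_signal", "viable"],
        ["tnfa_signal", "il10_signal"],
        "# units: tnfa_signal [MFI a.u.], il10_signal [MFI a.u.]",
    ),
    "droplets": (
        ["droplet_id", "n_cells"],
        ["n_cells"],
        "# units: n_cells [cells/droplet]",
    ),
    "elisa": (
        ["sample_id", "donor", "condition", "timepoint_h", "concentration_pg_ml",
         "volume_ml", "cell_count"],
        ["timepoint_h", "concentration_pg_ml", "volume_ml", "cell_count"],
        "# units: timepoint_h [h], concentration_pg_ml [pg/mL], volume_ml [mL], cell_count [cells]",
    ),
    "timecourse": (
        ["donor", "condition", "timepoint_h", "amount_pg_per_1e5_cells"],
        ["timepoint_h", "amount_pg_per_1e5_cells"],
        "# units: timepoint_h [h], amount_pg_per_1e5_cells [pg per 1e5 cells]",
    ),
    "rates": (
        ["t_start_h", "t_end_h", "rate_pg_per_h", "clearance"],
        ["t_start_h", "t_end_h", "rate_pg_per_h"],
        "# units: t_start_h [h], t_end_h [h], rate_pg_per_h [pg/h per 1e5 cells]",
    ),
    "predictions": (
        ["a", "fraction_pct"],
        ["a", "fraction_pct"],
        "# units: a [cells/droplet], fractions [%]",
    ),
}


def read_table(path) -> pd.DataFrame:
    """Read a package CSV, skipping the leading units comment line."""
    return pd.read_csv(path, comment="#")


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a CSV with a units comment header; stable float formatting.

    The fixed ``%.10g`` float format makes repeated writes of identical
    frames byte-identical, which the run manifest relies on.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if schema is not None and schema in SCHEMAS:
            fh.write(SCHEMAS[schema][2] + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def validate_frame(df: pd.DataFrame, schema: str) -> list[str]:
    """Schema-check an in-memory table; returns a list of violations."""
    if schema not in SCHEMAS:
        raise DropqsError(f"unknown schema '{schema}' (known: {sorted(SCHEMAS)})")
    required, numeric, _ = SCHEMAS[schema]
    violations = [f"missing required column '{c}'" for c in required if c not in df.columns]
    for c in numeric:
        if c in df.columns and not np.issubdtype(pd.to_numeric(df[c], errors="coerce").dtype, np.number):
            violations.append(f"column '{c}' is not numeric")
        elif c in df.columns and pd.to_numeric(df[c], errors="coerce").isna().any():
            bad = int(pd.to_numeric(df[c], errors="coerce").isna().idxmax())
            violations.append(f"column '{c}' has a non-numeric value at row {bad}")
    if not violations:
        if schema == "standards":
            for cytokine, grp in df.groupby("cytokine"):
                conc = grp["concentration_pg_ml"].to_numpy(dtype=float)
                mfi = grp["mfi"].to_numpy(dtype=float)
                for i in range(len(grp) - 1):
                    if conc[i + 1] <= conc[i]:
                        violations.append(
                            f"{cytokine}: concentrations not strictly increasing at row {i + 1}"
                        )
                    if mfi[i + 1] <= mfi[i]:
                        violations.append(
                            f"{cytokine}: mfi not strictly increasing at row {i + 1}"
                        )
        elif schema == "events":
            if df["cell_id"].duplicated().any():
                violations.append("cell_id values are not unique")
            for c in ("tnfa_signal", "il10_signal"):
                if (df[c].to_numpy(dtype=float) < 0).any():
                    violations.append(f"column '{c}' contains negative signals")
        elif schema in ("timecourse", "elisa"):
            keys = ["donor", "condition"] + (["cytokine"] if "cytokine" in df.columns else [])
            for key, grp in df.groupby(keys):
                t = grp["timepoint_h"].to_numpy(dtype=float)
                if np.any(np.diff(t) <= 0):
                    violations.append(f"group {key}: timepoints not strictly increasing")
        elif schema == "droplets":
            if (df["n_cells"].to_numpy(dtype=float) < 0).any():
                violations.append("n_cells contains negative counts")
    return violations


def validate_csv(path, schema: str) -> list[str]:
    """Validate a CSV file on disk against a named schema.

    Unreadable files raise (an I/O problem, distinct from a schema
    violation); schema problems are returned as a list of messages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = read_table(path)
    return validate_frame(df, schema)
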