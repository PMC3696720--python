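"""Delimited-text I/O for condition tables and trial logs.

All files are comma-separated UTF-8 with a header row and "." decimal
separator.  Condition tables use the columns

    label, mean_ms, sd_ms, cv, foreperiod_s, fp_observed, n

with empty cells where a value is optional (exactly one of sd_ms / cv
per row).  Probabilities are stored as fractions; percent appears only
in human-readable reports.  Numeric output is written to 6 significant
digits, which round-trips at that precision.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .imputation import ConditionStats
from .simulate import TrialRecord

CONDITION_COLUMNS = ["label", "mean_ms", "sd_ms", "cv", "foreperiod_s", "fp_observed", "n"]
TRIAL_COLUMNS = [
    "condition", "foreperiod_s", "trial_type", "latent_state", "rt_ms", "commission", "omission",
]


class TableFormatError(ValueError):
    """A condition table violated the expected schema."""


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def read_conditions(path: str | Path) -> list[ConditionStats]:
    """Parse a condition table, reporting schema errors with row numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise TableFormatError(f"{path}: not a readable condition table ({exc})") from exc
    missing = {"label", "mean_ms"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    if len(df) == 0:
        raise TableFormatError(f"{path}: table has a header but no data rows")
    out = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1

        def get(col, cast=float):
            val = row.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                return None
            return cast(val)

        try:
            out.append(
                ConditionStats(
                    label=str(row["label"]),
                    mean_rt=get("mean_ms"),
                    sd_rt=get("sd_ms"),
                    cv=get("cv"),
                    foreperiod=get("foreperiod_s") or 0.0,
                    fp_observed=get("fp_observed"),
                    n=get("n", int),
                    flag=get("flag", str) if "flag" in df.columns else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}, line {line}: {exc}") from exc
    return out


def write_conditions(conditions: list[ConditionStats], path: str | Path,
                     extra: dict[str, list] | None = None) -> None:
    """Write a condition table, optionally with appended columns."""
    rows = []
    for c in conditions:
        # a cv row keeps its cv cell and leaves sd_ms empty (and vice
        # versa) so the file re-parses under the one-dispersion rule
        rows.append({
            "label": c.label, "mean_ms": c.mean_rt,
            "sd_ms": c.sd_rt if c.cv is None else None, "cv": c.cv,
            "foreperiod_s": c.foreperiod, "fp_observed": c.fp_observed, "n": c.n,
            "flag": c.flag,
        })
    columns = list(CONDITION_COLUMNS)
    if any(c.flag is not None for c in conditions):
        columns.append("flag")
    df = pd.DataFrame(rows, columns=columns)
    for col, values in (extra or {}).items():
        df[col] = values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write(",".join(_fmt(v) for v in row.tolist()) + "\n")


def write_trials(trials: list[TrialRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(TRIAL_COLUMNS) + "\n")
        for tr in trials:
            fh.write(",".join(_fmt(v) for v in (
                tr.condition, tr.foreperiod, tr.trial_type, tr.latent_state_at_target,
                tr.rt, tr.commission, tr.omission,
            )) + "\n")


def read_trials(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        rt = row["rt_ms"]
        out.append(
            TrialRecord(
                condition=str(row["condition"]),
                foreperiod=float(row["foreperiod_s"]),
                trial_type=str(row["trial_type"]),
                latent_state_at_target=str(row["latent_state"]),
                rt=None if math.isnan(rt) else float(rt),
                commission=bool(row["commission"]),
                omission=bool(row["omission"]),
            )
        )
    return out


def write_curve(steps, probabilities, path: str | Path) -> None:
    """Two-column (step, probability) export for occupancy/error curves."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("step,probability\n")
        for k, p in zip(steps, probabilities):
            fh.write(f"{k},{_fmt(float(p))}\n")
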