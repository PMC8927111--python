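"""Derived analysis variables from raw measurements.

Anthropometrics (BMI = weight/height^2, waist-hip ratio, obesity and
overweight flags), substance-use indicators (packyears, high-consumption
flags), questionnaire sum scores and their internal consistency
(Cronbach's alpha).  All derivations are pure functions of the raw
columns: re-deriving is idempotent.

Threshold conventions: high tobacco consumption is >= 20 cigarettes/day and
high alcohol consumption >= 15 g/day by default (the inclusive forms);
``strict=True`` switches both to strict inequalities.  Overweight is
inclusive of obesity (BMI >= 25 for adults), so obesity implies overweight.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "derive_anthropometrics",
    "derive_smoking",
    "derive_alcohol",
    "sum_score",
    "cronbach_alpha",
    "derive_all",
    "write_derived",
]

log = logging.getLogger(__name__)

ADULT_AGE = 18.0
BMI_OBESE = 30.0
BMI_OVERWEIGHT = 25.0
Z_OBESE = 2.0
Z_OVERWEIGHT = 1.0
CIGARETTES_HIGH = 20.0
ALCOHOL_HIGH_G = 15.0
PACK_SIZE = 20.0


def _flag(series: pd.Series, cutoff: float, strict: bool) -> pd.Series:
    """Boolean-ish flag preserving missingness (float with NaN)."""
    out = (series > cutoff) if strict else (series >= cutoff)
    return out.astype(float).where(series.notna())


def child_bmi_zscore(
    bmi: pd.Series, age: pd.Series, sex: pd.Series, reference: pd.DataFrame
) -> pd.Series:
    """BMI z-scores for children against an age x sex reference table.

    ``reference`` has columns age (integer years), sex ('male'/'female')
    and either mean/sd or LMS columns L/M/S.  Ages are matched to the
    nearest reference age.
    """
    ref = reference.copy()
    lms = {"L", "M", "S"}.issubset(ref.columns)
    out = pd.Series(np.nan, index=bmi.index)
    for sx, grp in ref.groupby("sex"):
        sel = (sex.astype(str) == sx) & bmi.notna() & age.notna()
        if not sel.any():
            continue
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy(float)
        pos = np.clip(
            np.searchsorted(ages, age[sel].to_numpy(float)), 0, len(ages) - 1
        )
        prev = np.clip(pos - 1, 0, len(ages) - 1)
        nearer = np.where(
            np.abs(ages[pos] - age[sel].to_numpy(float))
            <= np.abs(ages[prev] - age[sel].to_numpy(float)),
            pos,
            prev,
        )
        b = bmi[sel].to_numpy(float)
        if lms:
            L = grp["L"].to_numpy(float)[nearer]
            M = grp["M"].to_numpy(float)[nearer]
            S = grp["S"].to_numpy(float)[nearer]
            z = np.where(
                np.abs(L) > 1e-8,
                ((b / M) ** L - 1.0) / (L * S),
                np.log(b / M) / S,
            )
        else:
            z = (b - grp["mean"].to_numpy(float)[nearer]) / grp["sd"].to_numpy(float)[nearer]
        out.loc[sel] = z
    return out


def derive_anthropometrics(
    t: pd.DataFrame,
    child_reference: pd.DataFrame | None = None,
    adult_age: float = ADULT_AGE,
) -> pd.DataFrame:
    """Add bmi, whr, obesity and overweight columns.

    BMI = weight (kg) / height (m)^2; WHR = waist / hip.  Adults: obesity
    is BMI >= 30, overweight BMI >= 25 (inclusive of obesity).  Individuals
    younger than ``adult_age`` are classified on BMI z-scores against
    ``child_reference`` (obesity z >= 2, overweight z >= 1); without a
    reference their flags stay missing.  Rows with non-positive height are
    flagged invalid and excluded from the derived columns.
    """
    out = t.copy()
    bad = out["height"].notna() & (out["height"] <= 0)
    if bad.any():
        log.warning("derive_anthropometrics: %d rows with non-positive height excluded", bad.sum())
    out["invalid_anthro"] = bad
    height = out["height"].where(~bad)
    out["bmi"] = out["weight"] / height**2
    if {"waist", "hip"}.issubset(out.columns):
        hip = out["hip"].where(out["hip"] > 0)
        out["whr"] = out["waist"] / hip

    is_child = out["age"] < adult_age
    obesity = _flag(out["bmi"], BMI_OBESE, strict=False)
    overweight = _flag(out["bmi"], BMI_OVERWEIGHT, strict=False)
    if is_child.any():
        if child_reference is not None:
            z = child_bmi_zscore(
                out.loc[is_child, "bmi"], out.loc[is_child, "age"],
                out.loc[is_child, "sex"], child_reference,
            )
            obesity.loc[is_child] = _flag(z, Z_OBESE, strict=False)
            overweight.loc[is_child] = _flag(z, Z_OVERWEIGHT, strict=False)
        else:
            log.warning(
                "derive_anthropometrics: %d children without a z-score reference; "
                "their obesity/overweight flags are missing", int(is_child.sum()),
            )
            obesity.loc[is_child] = np.nan
            overweight.loc[is_child] = np.nan
    out["obesity"] = obesity
    out["overweight"] = overweight
    return out


def derive_smoking(t: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Add tobacco_high flag and packyears.

    One packyear is 20 cigarettes/day for 1 year, so
    packyears = (cigarettes_per_day / 20) * years_smoked.  High consumption
    is >= 20 cigarettes/day (``strict=True``: > 20).  Negative counts flag
    the row invalid.
    """
    out = t.copy()
    neg = (out["cigarettes_per_day"] < 0) | (out.get("years_smoked", pd.Series(0, index=out.index)) < 0)
    if neg.any():
        log.warning("derive_smoking: %d rows with negative counts excluded", int(neg.sum()))
    out["invalid_smoking"] = neg.fillna(False)
    cpd = out["cigarettes_per_day"].where(~out["invalid_smoking"])
    out["tobacco_high"] = _flag(cpd, CIGARETTES_HIGH, strict)
    if "years_smoked" in out:
        out["packyears"] = (cpd / PACK_SIZE) * out["years_smoked"].where(~out["invalid_smoking"])
    return out


def derive_alcohol(t: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Add alcohol_high flag: daily intake >= 15 g (``strict=True``: > 15)."""
    out = t.copy()
    neg = out["daily_alcohol_g"] < 0
    if neg.any():
        log.warning("derive_alcohol: %d rows with negative intake excluded", int(neg.sum()))
    out["invalid_alcohol"] = neg.fillna(False)
    intake = out["daily_alcohol_g"].where(~out["invalid_alcohol"])
    out["alcohol_high"] = _flag(intake, ALCOHOL_HIGH_G, strict)
    return out


def sum_score(t: pd.DataFrame, items: Sequence[str], name: str = "sum_score") -> pd.Series:
    """Sum of binary 0/1 item columns; missing if any item is missing.

    Raises on non-binary item values.
    """
    vals = t[list(items)]
    observed = vals.stack()
    if not observed.isin([0, 1]).all():
        bad = sorted(set(observed[~observed.isin([0, 1])]))
        raise ValueError(f"non-binary item values: {bad[:5]}")
    score = vals.sum(axis=1).where(vals.notna().all(axis=1))
    score.name = name
    return score


def cronbach_alpha(t: pd.DataFrame, items: Sequence[str]) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(var_item) / var_total).

    Complete-case over the item columns; sample variances (n-1).  Raises
    when fewer than 2 items or 2 complete rows are available, or when the
    total-score variance is zero.
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    data = t[items].dropna()
    if len(data) < 2:
        raise ValueError("Cronbach's alpha needs at least 2 complete rows")
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("Cronbach's alpha undefined: zero total-score variance")
    k = len(items)
    return float(k / (k - 1) * (1.0 - data.var(ddof=1).sum() / total_var))


def write_derived(t: pd.DataFrame, path) -> None:
    """Write a derived phenotype table as TSV with a provenance header line.

    The output file name gets a ``derived_`` prefix.
    """
    from pathlib import Path

    from . import __version__

    path = Path(path)
    out = path.with_name(f"derived_{path.name}")
    with open(out, "w") as fh:
        fh.write(f"# derived phenotype table | kinstats {__version__}\n")
        t.to_csv(fh, sep="\t", index=False)


def derive_all(
    t: pd.DataFrame,
    child_reference: pd.DataFrame | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Run every derivation whose raw columns are present."""
    out = t
    if {"weight", "height"}.issubset(out.columns):
        out = derive_anthropometrics(out, child_reference)
    if "cigarettes_per_day" in out.columns:
        out = derive_smoking(out, strict)
    if "daily_alcohol_g" in out.columns:
        out = derive_alcohol(out, strict)
    return out
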