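"""Cohort exclusions, diagnostic classification and prevalence tables.

Implements the epidemiological tail of the screening pipeline: apply the
exclusion flowchart (L1 not in scan; fracture / surgical implant /
vertebroplasty), classify measured trabecular vBMD by the ACR QCT criteria
(osteoporosis < 80 mg/cm3, osteopenia 80-120 mg/cm3, normal > 120 mg/cm3 —
both printed boundaries fall in osteopenia), stratify by sex and 5-year age
bin (median and IQR), and compute crude and directly age-standardized
prevalence among participants at or above a minimum age (default 50).

Records travel as a pandas DataFrame with the column schema

    id, age, sex ("male"/"female"), flag_missing_L1, flag_fracture_implant,
    vbmd (mg/cm3, absent until measured), category (absent until classified)

Quartiles use linear interpolation (the "type 7" convention), recorded in
report metadata.  Display rounding is one decimal, half-up; internal values
are kept unrounded.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

OSTEOPOROSIS = "osteoporosis"
OSTEOPENIA = "osteopenia"
NORMAL = "normal"
CATEGORIES = (OSTEOPOROSIS, OSTEOPENIA, NORMAL)

ACR_OSTEOPOROSIS_MAX = 80.0  # exclusive upper bound for osteoporosis
ACR_OSTEOPENIA_MAX = 120.0  # inclusive upper bound for osteopenia

QUANTILE_CONVENTION = "linear interpolation (type 7)"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding: one decimal, half-up (so 34.45 -> 34.5)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# exclusions
# --------------------------------------------------------------------------

def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove flagged participants; tally counts per reason.

    A record with both flags set is excluded once and counted under the first
    flowchart reason (missing L1).  Conservation: included + tally total =
    input size.
    """
    n = len(records)
    if n == 0:
        return records.copy(), {"missing_L1": 0, "fracture_implant": 0, "total": 0}
    missing = records["flag_missing_L1"].astype(bool)
    fracture = records["flag_fracture_implant"].astype(bool) & ~missing
    included = records[~(missing | fracture)].copy()
    tally = {
        "missing_L1": int(missing.sum()),
        "fracture_implant": int(fracture.sum()),
        "total": int(missing.sum() + fracture.sum()),
    }
    assert len(included) + tally["total"] == n
    return included, tally


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_acr(vbmd: float) -> str:
    """ACR QCT category for one vBMD value (mg/cm3)."""
    if not np.isfinite(vbmd) or vbmd <= 0:
        raise ValueError(f"vBMD must be finite and positive, got {vbmd!r}")
    if vbmd < ACR_OSTEOPOROSIS_MAX:
        return OSTEOPOROSIS
    if vbmd <= ACR_OSTEOPENIA_MAX:
        return OSTEOPENIA
    return NORMAL


def classify_acr_series(vbmd: pd.Series) -> pd.Series:
    arr = vbmd.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("all vBMD values must be finite and positive")
    out = np.where(arr < ACR_OSTEOPOROSIS_MAX, OSTEOPOROSIS,
                   np.where(arr <= ACR_OSTEOPENIA_MAX, OSTEOPENIA, NORMAL))
    return pd.Series(out, index=vbmd.index, name="category")


# --------------------------------------------------------------------------
# age binning and the standard population
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeBinning:
    """5-year bins from ``start`` with an open-ended last bin."""

    start: int = 20
    last_edge: int = 85  # last closed edge; final bin is [last_edge, inf)

    @property
    def edges(self) -> list[float]:
        return list(range(self.start, self.last_edge + 1, 5)) + [np.inf]

    @property
    def labels(self) -> list[str]:
        out = [f"{lo}~{lo + 4}" for lo in range(self.start, self.last_edge, 5)]
        out.append(f"{self.last_edge}~")
        return out

    def label_of(self, age: float) -> str:
        if age < self.start:
            raise ValueError(f"age {age} below binning start {self.start}")
        if age >= self.last_edge:
            return f"{self.last_edge}~"
        lo = self.start + 5 * int((age - self.start) // 5)
        return f"{lo}~{lo + 4}"

    def assign(self, ages: pd.Series) -> pd.Series:
        return ages.map(self.label_of)


@dataclass
class StandardPopulation:
    """Age-bin weights for direct standardization, with a provenance label."""

    weights: dict[str, float]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        for label, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for bin {label!r}")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("weights must sum to a positive value")

    @staticmethod
    def from_csv(path, name: str | None = None) -> "StandardPopulation":
        df = pd.read_csv(path, comment="#")
        weights = dict(zip(df["bin_label"].astype(str), df["weight"].astype(float)))
        return StandardPopulation(weights=weights, name=name or str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"bin_label": list(self.weights), "weight": list(self.weights.values())}
        ).to_csv(path, index=False)


def synthetic_standard_population() -> StandardPopulation:
    """The bundled synthetic reference population (50+ bins).

    A smooth stand-in age pyramid for an aging population; it is *not* any
    real census table, and every report that uses it says so via the
    provenance label.
    """
    from importlib.resources import files

    path = files("qctscreen").joinpath("data/synthetic_standard_population.csv")
    with path.open("rb") as fh:
        df = pd.read_csv(fh, comment="#")
    weights = dict(zip(df["bin_label"].astype(str), df["weight"].astype(float)))
    return StandardPopulation(weights=weights, name="synthetic-reference-population")


# --------------------------------------------------------------------------
# stratified descriptive table
# --------------------------------------------------------------------------

def stratify_bmd(records: pd.DataFrame, binning: AgeBinning | None = None) -> pd.DataFrame:
    """Per-bin, per-sex median and IQR of vBMD.

    One row per age bin with n/median/q1/q3 for both sexes combined and for
    each sex.  Empty cells report n = 0 with absent (NaN) statistics, never
    fabricated zeros.  Quartiles use linear interpolation.
    """
    binning = binning or AgeBinning()
    if records["vbmd"].isna().any():
        raise ValueError("every record needs a measured vbmd before stratification")
    df = records.copy()
    df["age_bin"] = binning.assign(df["age"])
    rows = []
    for label in binning.labels:
        row: dict[str, object] = {"age_bin": label}
        in_bin = df[df["age_bin"] == label]
        for group, sub in (
            ("both", in_bin),
            ("female", in_bin[in_bin["sex"] == "female"]),
            ("male", in_bin[in_bin["sex"] == "male"]),
        ):
            vals = sub["vbmd"].to_numpy(dtype=float)
            row[f"n_{group}"] = len(vals)
            if len(vals) == 0:
                row[f"median_{group}"] = np.nan
                row[f"q1_{group}"] = np.nan
                row[f"q3_{group}"] = np.nan
            else:
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="linear")
                row[f"median_{group}"] = med
                row[f"q1_{group}"] = q1
                row[f"q3_{group}"] = q3
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["quantile_convention"] = QUANTILE_CONVENTION
    return out


# --------------------------------------------------------------------------
# prevalence
# --------------------------------------------------------------------------

UNDEFINED = None  # marker for prevalence over an empty denominator


def crude_prevalence(
    records: pd.DataFrame, min_age: int = 50
) -> dict[str, dict[str, object]]:
    """Crude category prevalence among participants aged >= ``min_age``.

    Returns, for each of "combined"/"male"/"female": the denominator ``n``,
    per-category counts, and per-category percentages (unrounded; ``None``
    when the denominator is empty — an undefined prevalence is never
    reported as 0%).
    """
    if "category" not in records.columns or records["category"].isna().any():
        raise ValueError("all records must be classified before computing prevalence")
    eligible = records[records["age"] >= min_age]
    out: dict[str, dict[str, object]] = {}
    for group, sub in (
        ("combined", eligible),
        ("male", eligible[eligible["sex"] == "male"]),
        ("female", eligible[eligible["sex"] == "female"]),
    ):
        n = len(sub)
        counts = {c: int((sub["category"] == c).sum()) for c in CATEGORIES}
        pct = {c: (100.0 * counts[c] / n if n > 0 else UNDEFINED) for c in CATEGORIES}
        out[group] = {"n": n, "counts": counts, "pct": pct}
    return out


def per_bin_prevalence(
    records: pd.DataFrame,
    category: str,
    binning: AgeBinning | None = None,
    min_age: int = 50,
    sex: str | None = None,
) -> dict[str, float]:
    """Prevalence (%) of ``category`` per age bin, bins with data only."""
    binning = binning or AgeBinning()
    df = records[records["age"] >= min_age]
    if sex is not None:
        df = df[df["sex"] == sex]
    out: dict[str, float] = {}
    labels = binning.assign(df["age"]) if len(df) else pd.Series(dtype=object)
    for label in binning.labels:
        sub = df[labels == label] if len(df) else df
        if len(sub) == 0:
            continue
        out[label] = 100.0 * (sub["category"] == category).sum() / len(sub)
    return out


def age_standardize(
    prevalence_by_bin: dict[str, float],
    standard: StandardPopulation,
) -> tuple[float, str]:
    """Directly age-standardized prevalence (%).

    Computes the weighted average of per-bin prevalences using the standard
    population's weights.  Weights are renormalized over the bins that have
    observed prevalence; when the cohort lacks bins the standard covers, a
    warning notes the renormalization.  Returns the value and the standard's
    provenance label.
    """
    if not prevalence_by_bin:
        raise ValueError("no per-bin prevalences to standardize")
    missing = [b for b in prevalence_by_bin if b not in standard.weights]
    if missing:
        raise ValueError(f"standard population lacks weights for bins {missing}")
    covered = {b: standard.weights[b] for b in prevalence_by_bin}
    for b, w in covered.items():
        if w < 0:
            raise ValueError(f"negative weight for bin {b!r}")
    uncovered = set(standard.weights) - set(prevalence_by_bin)
    total = sum(covered.values())
    if total <= 0:
        raise ValueError("covered bins carry zero total weight")
    if uncovered and abs(sum(standard.weights.values()) - total) > 1e-12:
        warnings.warn(
            f"cohort lacks bins {sorted(uncovered)}; weights renormalized over covered bins",
            stacklevel=2,
        )
    value = sum(w / total * prevalence_by_bin[b] for b, w in covered.items())
    return float(value), standard.name


@dataclass
class PrevalenceReport:
    """Crude and age-standardized prevalence, per sex and combined."""

    table: pd.DataFrame  # group, category, n, count, crude_pct, standardized_pct
    min_age: int
    standard_name: str
    per_bin: dict[str, dict[str, dict[str, float]]]  # group -> category -> bin -> %
    quantile_convention: str = QUANTILE_CONVENTION

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"Prevalence among participants aged >= {self.min_age}\n")
        buf.write(f"Age-standardized to: {self.standard_name}\n\n")
        for group in ("combined", "male", "female"):
            sub = self.table[self.table["group"] == group]
            if sub.empty:
                continue
            n = int(sub["n"].iloc[0])
            buf.write(f"{group} (n = {n}):\n")
            for _, r in sub.iterrows():
                crude = "undefined" if pd.isna(r["crude_pct"]) else f"{round_half_up(r['crude_pct']):.1f}%"
                std = "undefined" if pd.isna(r["standardized_pct"]) else f"{round_half_up(r['standardized_pct']):.1f}%"
                buf.write(
                    f"  {r['category']:<13} {int(r['count']):>5}  crude {crude:>9}"
                    f"  age-standardized {std:>9}\n"
                )
            buf.write("\n")
        return buf.getvalue()


def prevalence_report(
    records: pd.DataFrame,
    standard: StandardPopulation | None = None,
    min_age: int = 50,
    binning: AgeBinning | None = None,
) -> PrevalenceReport:
    """Build the crude + age-standardized prevalence report."""
    standard = standard or synthetic_standard_population()
    binning = binning or AgeBinning()
    crude = crude_prevalence(records, min_age=min_age)
    rows = []
    per_bin_all: dict[str, dict[str, dict[str, float]]] = {}
    for group in ("combined", "male", "female"):
        sex = None if group == "combined" else group
        per_bin_all[group] = {}
        for category in (OSTEOPOROSIS, OSTEOPENIA):
            pbp = per_bin_prevalence(records, category, binning, min_age=min_age, sex=sex)
            per_bin_all[group][category] = pbp
            if pbp:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    std_val, _ = age_standardize(pbp, standard)
            else:
                std_val = np.nan
            crude_pct = crude[group]["pct"][category]
            rows.append(
                {
                    "group": group,
                    "category": category,
                    "n": crude[group]["n"],
                    "count": crude[group]["counts"][category],
                    "crude_pct": np.nan if crude_pct is UNDEFINED else crude_pct,
                    "standardized_pct": std_val,
                }
            )
    table = pd.DataFrame(rows)
    return PrevalenceReport(
        table=table,
        min_age=min_age,
        standard_name=standard.name,
        per_bin=per_bin_all,
    )
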