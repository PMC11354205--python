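"""Phantom-based HU-to-BMD calibration.

A spine phantom with inserts of known bone-equivalent density (default
50/100/200 mg/cc) is scanned under the same protocol as the patients
(asynchronous calibration).  Per insert and per axial slice a trimmed-median
representative HU is extracted; six candidate regressions of density on HU are
fitted; each candidate's in-sample RMSE (mg/cc) is computed; the lowest-RMSE
candidate is selected, unless even the best exceeds the recalibration
threshold (5.0 mg/cc), in which case a recalibration signal is returned
instead of a model.

Candidate families
------------------
linear         BMD = b1*HU + b0
quadratic      BMD = b2*HU^2 + b1*HU + b0
power          BMD = a * HU^b           (HU > 0 required)
logarithmic    BMD = a + b*ln(HU)       (HU > 0 required)
exponential    BMD = a * exp(b*HU)
robust_linear  Theil-Sen: median of pairwise slopes

The family set is recorded in the serialized model so results are
self-describing.  A fitted model is checked for monotonicity over its HU
domain (observed range +/- 50 HU); a BMD conversion should be
order-preserving, so non-monotone candidates are flagged and lose RMSE ties.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    CalibrationFailureError,
    DomainError,
    InsufficientSamplesError,
)
from .volume import CTVolume, superior_axis

if TYPE_CHECKING:  # pragma: no cover
    pass

DEFAULT_RMSE_THRESHOLD = 5.0  # mg/cc; "exceeded" is strict
DOMAIN_PAD_HU = 50.0
METHODS = ("linear", "quadratic", "power", "logarithmic", "exponential", "robust_linear")


@dataclass
class PhantomScan:
    """A phantom volume with its insert masks and known densities."""

    volume: CTVolume
    insert_masks: Sequence[np.ndarray]
    insert_densities: tuple[float, float, float]
    protocol: str = "default"

    def __post_init__(self) -> None:
        if len(self.insert_masks) != len(self.insert_densities):
            raise ValueError("one mask per insert density required")
        if list(self.insert_densities) != sorted(self.insert_densities):
            raise ValueError("insert densities must be strictly increasing")
        if len(set(self.insert_densities)) != len(self.insert_densities):
            raise ValueError("insert densities must be distinct")
        for i, m in enumerate(self.insert_masks):
            if m.shape != self.volume.shape:
                raise ValueError(f"insert mask {i} not congruent with volume")
            if not m.any():
                raise ValueError(f"insert mask {i} is empty")
        for i in range(len(self.insert_masks)):
            for j in range(i + 1, len(self.insert_masks)):
                if (self.insert_masks[i] & self.insert_masks[j]).any():
                    raise ValueError(f"insert masks {i} and {j} overlap")


@dataclass
class CalibrationSamples:
    """Per-insert, per-slice representative HU rows for regression."""

    rows: pd.DataFrame  # columns: density, slice_index, hu
    protocol: str = "default"

    def __post_init__(self) -> None:
        required = {"density", "slice_index", "hu"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"rows must have columns {sorted(required)}")
        if len(self.rows) < 3:
            raise ValueError("need at least 3 calibration rows")
        if not np.all(np.isfinite(self.rows["hu"])):
            raise ValueError("HU values must be finite")

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @staticmethod
    def from_csv(path, protocol: str = "default") -> "CalibrationSamples":
        return CalibrationSamples(rows=pd.read_csv(path), protocol=protocol)


@dataclass
class ConversionModel:
    """A fitted HU -> BMD conversion equation."""

    method: str
    coefficients: tuple[float, ...]
    rmse: float
    protocol: str = "default"
    hu_domain: tuple[float, float] = (-2000.0, 4000.0)
    monotone: bool = True

    def predict(self, hu) -> np.ndarray:
        hu = np.asarray(hu, dtype=float)
        c = self.coefficients
        if self.method == "linear":
            return c[0] * hu + c[1]
        if self.method == "robust_linear":
            return c[0] * hu + c[1]
        if self.method == "quadratic":
            return c[0] * hu**2 + c[1] * hu + c[2]
        if self.method == "power":
            return c[0] * np.power(hu, c[1])
        if self.method == "logarithmic":
            return c[0] + c[1] * np.log(hu)
        if self.method == "exponential":
            return c[0] * np.exp(c[1] * hu)
        raise ValueError(f"unknown method {self.method!r}")

    def to_json(self, path=None) -> str:
        doc = {
            "format": "qctscreen-conversion-model",
            "version": 1,
            "method": self.method,
            "coefficients": list(self.coefficients),
            "rmse_mg_cc": self.rmse,
            "protocol": self.protocol,
            "hu_domain": list(self.hu_domain),
            "monotone": self.monotone,
            "candidate_families": list(METHODS),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @staticmethod
    def from_json(path) -> "ConversionModel":
        with open(path) as fh:
            doc = json.load(fh)
        return ConversionModel(
            method=doc["method"],
            coefficients=tuple(doc["coefficients"]),
            rmse=float(doc["rmse_mg_cc"]),
            protocol=doc["protocol"],
            hu_domain=tuple(doc["hu_domain"]),
            monotone=bool(doc["monotone"]),
        )


@dataclass
class RecalibrationNeeded:
    """Signal that even the best candidate exceeded the RMSE threshold.

    The phantom must be re-scanned to obtain a new set of HU samples; an
    over-threshold model is never returned silently.
    """

    best_rmse: float
    threshold: float
    best_method: str


@dataclass
class FitFailure:
    method: str
    reason: str


def extract_insert_hu(phantom: PhantomScan, trim_fraction: float = 0.01) -> CalibrationSamples:
    """Per-insert, per-slice trimmed-median HU rows.

    Uses the same trimmed-median operator as the patient measurement so the
    calibration and the measurement share one representative-HU definition.
    Each insert must intersect at least 3 axial slices.
    """
    from .bmd_measure import trimmed_median  # local import avoids a cycle

    s_ax, _ = superior_axis(phantom.volume.orientation)
    vox = phantom.volume.voxels
    records = []
    for mask, density in zip(phantom.insert_masks, phantom.insert_densities):
        slices = np.unique(np.nonzero(mask)[s_ax])
        if len(slices) < 3:
            raise InsufficientSamplesError(
                f"insert at density {density} intersects only {len(slices)} slices (< 3)"
            )
        for k in slices:
            sl = [slice(None)] * 3
            sl[s_ax] = int(k)
            m2 = mask[tuple(sl)]
            values = vox[tuple(sl)][m2]
            rep = trimmed_median(values, trim_fraction=trim_fraction)
            records.append({"density": density, "slice_index": int(k), "hu": rep.value})
    return CalibrationSamples(rows=pd.DataFrame.from_records(records), protocol=phantom.protocol)


def _refined_fit(func, hu, bmd, p0):
    popt, _ = optimize.curve_fit(func, hu, bmd, p0=p0, maxfev=10000)
    return tuple(float(p) for p in popt)


def _fit_one(method: str, hu: np.ndarray, bmd: np.ndarray) -> tuple[float, ...]:
    if method == "linear":
        b1, b0 = np.polyfit(hu, bmd, 1)
        return (float(b1), float(b0))
    if method == "quadratic":
        if len(np.unique(hu)) < 3:
            raise ValueError("quadratic fit needs >= 3 distinct HU values")
        b2, b1, b0 = np.polyfit(hu, bmd, 2)
        return (float(b2), float(b1), float(b0))
    if method == "power":
        if np.any(hu <= 0) or np.any(bmd <= 0):
            raise ValueError("power fit requires positive HU and BMD")
        lb, la = np.polyfit(np.log(hu), np.log(bmd), 1)
        return _refined_fit(lambda x, a, b: a * np.power(x, b), hu, bmd, (np.exp(la), lb))
    if method == "logarithmic":
        if np.any(hu <= 0):
            raise ValueError("logarithmic fit requires positive HU")
        b, a = np.polyfit(np.log(hu), bmd, 1)
        return (float(a), float(b))
    if method == "exponential":
        if np.any(bmd <= 0):
            raise ValueError("exponential fit requires positive BMD")
        lb, la = np.polyfit(hu, np.log(bmd), 1)
        return _refined_fit(lambda x, a, b: a * np.exp(b * x), hu, bmd, (np.exp(la), lb))
    if method == "robust_linear":
        res = stats.theilslopes(bmd, hu)
        return (float(res.slope), float(res.intercept))
    raise ValueError(f"unknown method {method!r}")


def _is_monotone(model: ConversionModel) -> bool:
    lo, hi = model.hu_domain
    if model.method in ("logarithmic", "power"):
        lo = max(lo, 1e-6)
    grid = np.linspace(lo, hi, 201)
    with np.errstate(all="ignore"):
        pred = model.predict(grid)
    pred = pred[np.isfinite(pred)]
    return len(pred) > 1 and bool(np.all(np.diff(pred) >= -1e-9))


def fit_conversion(
    samples: CalibrationSamples,
    methods: Sequence[str] = METHODS,
) -> tuple[list[ConversionModel], list[FitFailure]]:
    """Fit every candidate family; return candidates sorted by RMSE ascending.

    RMSE is the in-sample root mean squared error of predicted vs true insert
    density over all rows, in mg/cc.  Per-method failures (degenerate design,
    domain violations, non-convergence) are recorded, not fatal — unless every
    family fails, which raises :class:`CalibrationFailureError`.
    """
    df = samples.rows
    hu = df["hu"].to_numpy(dtype=float)
    bmd = df["density"].to_numpy(dtype=float)
    if len(np.unique(bmd)) < 3:
        raise ValueError("need >= 3 distinct insert densities")
    hu_domain = (float(hu.min() - DOMAIN_PAD_HU), float(hu.max() + DOMAIN_PAD_HU))

    candidates: list[ConversionModel] = []
    failures: list[FitFailure] = []
    for method in methods:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coef = _fit_one(method, hu, bmd)
            model = ConversionModel(
                method=method,
                coefficients=coef,
                rmse=0.0,
                protocol=samples.protocol,
                hu_domain=hu_domain,
            )
            pred = model.predict(hu)
            if not np.all(np.isfinite(pred)):
                raise ValueError("non-finite predictions on the calibration rows")
            model.rmse = float(np.sqrt(np.mean((pred - bmd) ** 2)))
            model.monotone = _is_monotone(model)
            candidates.append(model)
        except Exception as exc:  # noqa: BLE001 — per-method failure is data, not control flow
            failures.append(FitFailure(method=method, reason=str(exc)))
    if not candidates:
        raise CalibrationFailureError(
            "all candidate fits failed: " + "; ".join(f"{f.method}: {f.reason}" for f in failures)
        )
    candidates.sort(key=lambda m: (m.rmse, not m.monotone, m.method))
    return candidates, failures


def select_model(
    candidates: Sequence[ConversionModel],
    rmse_threshold: float = DEFAULT_RMSE_THRESHOLD,
) -> ConversionModel | RecalibrationNeeded:
    """Lowest-RMSE candidate, or a recalibration signal if even it exceeds the bound.

    The threshold comparison is strict: a candidate with RMSE exactly equal to
    the threshold is accepted ("exceeded" means > threshold).
    """
    if not candidates:
        raise CalibrationFailureError("no successfully fitted candidates to select from")
    best = min(candidates, key=lambda m: (m.rmse, not m.monotone, m.method))
    if best.rmse > rmse_threshold:
        return RecalibrationNeeded(
            best_rmse=best.rmse, threshold=rmse_threshold, best_method=best.method
        )
    return best


def convert_hu_to_bmd(model: ConversionModel, hu, clamp: bool = True) -> np.ndarray:
    """Evaluate the conversion equation; vectorized over ``hu``.

    Inputs outside ``model.hu_domain`` are clamped to it by default; with
    ``clamp=False`` they raise :class:`DomainError`.
    """
    arr = np.asarray(hu, dtype=float)
    lo, hi = model.hu_domain
    out_of_domain = (arr < lo) | (arr > hi)
    if out_of_domain.any():
        if not clamp:
            raise DomainError(
                f"HU values outside model domain [{lo:.1f}, {hi:.1f}] with clamping disabled"
            )
        arr = np.clip(arr, lo, hi)
    result = model.predict(arr)
    if not np.all(np.isfinite(result)):
        raise DomainError("conversion produced non-finite BMD values")
    return result if np.ndim(hu) else float(result)
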