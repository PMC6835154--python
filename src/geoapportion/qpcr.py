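"""Absolute qPCR quantification of the geosmin-synthase gene and total 16S.

Standard curves are ordinary least-squares fits of Cq on log10(copies);
quantities are recovered by inverting the fitted curve. QC gates follow
the assay acceptance rules: amplification efficiency > 90%, replicate
coefficient of variation < 30%, curve R^2 >= 0.98 (configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The four group assays targeting the geosmin-synthase gene. There is no
#: group-2 assay; the primer sets are numbered 1, 3, 4 and 5.
GEOA_GROUPS = ("g1", "g3", "g4", "g5")

#: Reporting unit expected for each compartment.
COMPARTMENT_UNITS = {
    "water": "mL",
    "mucous": "cm2",
    "digesta": "g",
    "fin": "cm2",
}


class InsufficientStandardsError(ValueError):
    """Raised when a standard series has fewer than three distinct levels."""


def efficiency_from_slope(slope: float) -> float:
    """Per-cycle amplification efficiency, ``10**(-1/slope) - 1``.

    A slope of -3.3219 (perfect doubling chemistry) gives 1.0 (100%).
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError(f"standard-curve slope must be finite and negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear Cq <-> copy-number relation.

    Attributes
    ----------
    slope : Cq per log10(copies); negative for any amplifying assay.
    intercept : Cq at a single copy.
    r2 : coefficient of determination of the fit.
    efficiency : per-cycle amplification factor minus one.
    n_points : number of standard wells used in the fit.
    """

    slope: float
    intercept: float
    r2: float = 1.0
    n_points: int = 0
    efficiency: float = field(init=False)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"slope must be negative, got {self.slope}")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")
        object.__setattr__(self, "efficiency", efficiency_from_slope(self.slope))

    def cq_of(self, copies: float) -> float:
        """Expected Cq for a template of ``copies`` molecules (copies > 0)."""
        if copies <= 0:
            raise ValueError("copies must be positive to evaluate the curve")
        return self.intercept + self.slope * math.log10(copies)


@dataclass
class GeoAQuant:
    """Per-sample quantification across the four group assays.

    ``total_copies`` is the arithmetic sum of the group results;
    ``concentration`` carries the compartment-native unit (per mL for
    water, per cm^2 for mucous/fin, per g for digesta).
    """

    sample_id: str
    group_copies: dict[str, float]
    total_copies: float
    compartment: str | None = None
    concentration: float | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        expected = sum_geoa_groups(self.group_copies)
        if not math.isclose(self.total_copies, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"total_copies {self.total_copies} != sum of groups {expected}"
            )
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.compartment is not None and self.unit is not None:
            want = COMPARTMENT_UNITS.get(self.compartment)
            if want is not None and self.unit != want:
                raise ValueError(
                    f"unit {self.unit!r} does not match compartment "
                    f"{self.compartment!r} (expected {want!r})"
                )


@dataclass(frozen=True)
class QcReport:
    """Assay QC verdicts; each pass flag is a pure function of the metrics."""

    efficiency: float
    replicate_cv: float
    r2: float
    efficiency_pass: bool
    cv_pass: bool
    r2_pass: bool
    flags: tuple[str, ...] = ()

    @property
    def all_pass(self) -> bool:
        return self.efficiency_pass and self.cv_pass and self.r2_pass


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS fit of Cq on log10(known copies) over a dilution series.

    Parameters
    ----------
    points : sequence of (known_copies, cq) pairs; at least three
        distinct copy levels, all copies strictly positive.

    Returns
    -------
    StandardCurve with slope, intercept, R^2 and efficiency populated.
    """
    if len(points) == 0:
        raise InsufficientStandardsError("no standard points supplied")
    copies = np.asarray([p[0] for p in points], dtype=float)
    cq = np.asarray([p[1] for p in points], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("standard copy numbers must be strictly positive")
    if not np.all(np.isfinite(cq)):
        raise ValueError("standard Cq values must be finite")
    if len(np.unique(copies)) < 3:
        raise InsufficientStandardsError(
            f"need >=3 distinct copy levels, got {len(np.unique(copies))}"
        )
    x = np.log10(copies)
    res = stats.linregress(x, cq)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=len(points),
    )


def quantify(cq: float | None, curve: StandardCurve) -> float:
    """Copies per reaction from a Cq value, ``10**((cq - intercept)/slope)``.

    ``None`` encodes a no-amplification well and maps to 0 copies.
    """
    if cq is None:
        return 0.0
    if not np.isfinite(cq):
        raise ValueError(f"Cq must be finite (use None for no amplification), got {cq}")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def qc_assay(
    curve: StandardCurve,
    replicate_copies: Sequence[float],
    *,
    min_efficiency: float = 0.90,
    max_cv: float = 0.30,
    min_r2: float = 0.98,
) -> QcReport:
    """QC an assay against the efficiency, replicate-CV and R^2 gates."""
    reps = np.asarray(replicate_copies, dtype=float)
    if reps.size < 2:
        raise ValueError("need >=2 replicates to compute a CV")
    flags: list[str] = []
    mean = float(reps.mean())
    if mean == 0.0:
        cv = float("nan")
        cv_pass = False
        flags.append("cv_undefined_all_zero")
    else:
        cv = float(reps.std(ddof=1) / mean)
        cv_pass = cv < max_cv
    eff_pass = curve.efficiency > min_efficiency
    if not eff_pass:
        flags.append("efficiency_low")
    r2_pass = curve.r2 >= min_r2
    if not r2_pass:
        flags.append("r2_low")
    if not cv_pass and mean != 0.0:
        flags.append("replicate_cv_high")
    return QcReport(
        efficiency=curve.efficiency,
        replicate_cv=cv,
        r2=curve.r2,
        efficiency_pass=eff_pass,
        cv_pass=cv_pass,
        r2_pass=r2_pass,
        flags=tuple(flags),
    )


def sum_geoa_groups(group_copies: Mapping[str, float]) -> float:
    """Total gene copies as the sum over the group assays.

    Missing groups count as absent (zero). Negative inputs are rejected.
    """
    unknown = set(group_copies) - set(GEOA_GROUPS)
    if unknown:
        raise ValueError(f"unknown assay groups: {sorted(unknown)}; expected {GEOA_GROUPS}")
    for g, v in group_copies.items():
        if v < 0:
            raise ValueError(f"negative copies for group {g}: {v}")
    # summation in canonical group order keeps the result permutation-invariant
    return float(sum(group_copies.get(g, 0.0) for g in GEOA_GROUPS))


def normalize_concentration(
    copies_per_reaction: float,
    sampled_size: float,
    *,
    scaling: float = 1.0,
    extraction_yield: float = 1.0,
    unit: str | None = None,
    compartment: str | None = None,
) -> float:
    """Convert copies per reaction to a concentration per mL, cm^2 or g.

    ``scaling`` is the elution-volume / template-fraction factor mapping a
    reaction back to the whole extract (a calibration knob; the assay
    protocol does not pin it down, default 1). ``extraction_yield`` is the
    recovered DNA fraction.

    concentration = copies * scaling / (extraction_yield * sampled_size)
    """
    if sampled_size <= 0:
        raise ValueError("sampled_size must be positive")
    if copies_per_reaction < 0:
        raise ValueError("copies_per_reaction must be non-negative")
    if not 0 < extraction_yield <= 1:
        raise ValueError("extraction_yield must be in (0, 1]")
    if unit is not None and compartment is not None:
        want = COMPARTMENT_UNITS.get(compartment)
        if want is not None and unit != want:
            raise ValueError(
                f"unit {unit!r} does not match compartment {compartment!r} "
                f"(expected {want!r})"
            )
    return copies_per_reaction * scaling / (extraction_yield * sampled_size)


def process_plate(
    plate: pd.DataFrame,
    *,
    geoa_assays: Sequence[str] = GEOA_GROUPS,
    total_assay: str = "16s",
) -> pd.DataFrame:
    """Quantify every unknown sample on a plate.

    The plate table carries one row per well with columns ``sample_id``,
    ``assay_id``, ``replicate``, ``cq`` (NaN = no amplification),
    ``is_standard`` and ``standard_copies``. Standards are pooled per
    assay to fit one curve; unknown replicate wells are quantified
    individually and averaged on the linear (copies) scale.

    Returns a tidy frame with one row per (sample_id, assay_id) holding
    mean copies per reaction, the replicate count and replicate CV.
    """
    required = {"sample_id", "assay_id", "replicate", "cq", "is_standard", "standard_copies"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    curves: dict[str, StandardCurve] = {}
    for assay, grp in plate[plate["is_standard"].astype(bool)].groupby("assay_id"):
        pts = [
            (row.standard_copies, row.cq)
            for row in grp.itertuples()
            if np.isfinite(row.cq)
        ]
        curves[assay] = fit_standard_curve(pts)

    rows = []
    unknowns = plate[~plate["is_standard"].astype(bool)]
    for (sample, assay), grp in unknowns.groupby(["sample_id", "assay_id"]):
        if assay not in curves:
            raise ValueError(f"no standard curve available for assay {assay!r}")
        curve = curves[assay]
        copies = [
            quantify(None if not np.isfinite(c) else float(c), curve)
            for c in grp["cq"]
        ]
        arr = np.asarray(copies)
        mean = float(arr.mean())
        cv = float(arr.std(ddof=1) / mean) if arr.size > 1 and mean > 0 else float("nan")
        rows.append(
            {
                "sample_id": sample,
                "assay_id": assay,
                "copies": mean,
                "n_replicates": int(arr.size),
                "replicate_cv": cv,
            }
        )
    out = pd.DataFrame(rows, columns=["sample_id", "assay_id", "copies", "n_replicates", "replicate_cv"])
    out.attrs["curves"] = curves
    return out


def summarize_geoa(
    per_assay: pd.DataFrame,
    *,
    geoa_assays: Sequence[str] = GEOA_GROUPS,
) -> pd.DataFrame:
    """Collapse per-assay copies into per-sample group sums.

    Expects the output of :func:`process_plate`; returns one row per
    sample with each group's copies and their ``total`` sum.
    """
    wide = per_assay.pivot_table(
        index="sample_id", columns="assay_id", values="copies", aggfunc="first"
    )
    for g in geoa_assays:
        if g not in wide.columns:
            wide[g] = 0.0
    wide = wide.fillna(0.0)
    wide["total"] = sum(wide[g] for g in geoa_assays)
    return wide.reset_index()
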