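"""Indirect competitive ELISA calibration and performance analysis.

Calibration uses the four-parameter logistic (4PL) model

    y(x) = d + (a - d) / (1 + (x / c)^b)

with ``a`` the response at zero analyte, ``d`` the response at infinite
analyte, ``c`` the inflection concentration (µg/mL) and ``b`` the slope
factor.  In the competitive format the response (OD450, or B/B0 when
normalized by the zero-analyte buffer control) decreases with analyte
concentration, so a > d and b > 0.

Performance metrics follow standard assay-validation practice:

* inhibition rate  = (OD_control - OD_sample) / OD_control * 100
* P/N ratio        = OD_positive / OD_negative; effective when strictly > 2.1
* LOD / LOQ        = blank mean + 3 SD / + 10 SD on the concentration scale
  (ten buffer blanks read through the fitted curve), with sample SD (n-1)
* food scale       : µg/mL in extract * extraction ratio (1 g sample : 10 mL
  buffer) = mg analyte per kg food
* milk-protein eq. : food scale / 0.10 (β-lactoglobulin is ~10% of milk
  protein)
* recovery         = measured / spiked * 100
* precision        : intra-assay CV over replicate extracts in one run,
  inter-assay CV over all cross-day values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError, NumericalError

logger = logging.getLogger(__name__)

__all__ = [
    "PLATE_COLUMNS",
    "PLATE_ROLES",
    "FourPLFit",
    "InversionResult",
    "DetectionLimits",
    "PrecisionPanel",
    "AssayAnalysis",
    "validate_plate",
    "eval_4pl",
    "fit_4pl",
    "fit_standard_curve",
    "normalize_b_over_b0",
    "invert_4pl",
    "inhibition_rate",
    "pn_series",
    "min_effective_concentration",
    "lod_loq",
    "convert_to_food",
    "milk_protein_equivalent",
    "recovery",
    "precision_panel",
    "censor_and_report",
    "analyze_plate",
    "plot_standard_curve",
]

PLATE_COLUMNS = ("well_id", "role", "concentration", "replicate", "od450")
PLATE_ROLES = ("standard", "blank", "sample", "negative_control")

DEFAULT_DILUTION_FACTOR = 10.0  # 1 g sample : 10 mL extraction buffer
DEFAULT_BLG_FRACTION = 0.10  # β-lactoglobulin share of milk protein
DEFAULT_PN_CUTOFF = 2.1


# ---------------------------------------------------------------------------
# Plate table
# ---------------------------------------------------------------------------


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a plate table; returns the validated frame.

    Required columns: well_id, role, concentration, replicate, od450.
    Standards must carry concentrations; OD450 must be finite and >= 0;
    (well_id, replicate) pairs must be unique.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise InputError(f"plate table missing columns {missing}")
    if len(plate) == 0:
        raise InputError("empty plate table")
    bad_roles = sorted(set(plate["role"]) - set(PLATE_ROLES))
    if bad_roles:
        raise InputError(f"unknown well roles {bad_roles}; expected {PLATE_ROLES}")
    od = pd.to_numeric(plate["od450"], errors="coerce")
    bad = plate.index[~np.isfinite(od) | (od < 0)].tolist()
    if bad:
        raise InputError(f"non-finite or negative od450 at rows {bad}")
    std = plate[plate["role"] == "standard"]
    conc = pd.to_numeric(std["concentration"], errors="coerce")
    if conc.isna().any():
        rows = std.index[conc.isna()].tolist()
        raise InputError(f"standards without a concentration at rows {rows}")
    if (conc < 0).any():
        rows = std.index[conc < 0].tolist()
        raise InputError(f"negative standard concentrations at rows {rows}")
    dup = plate.duplicated(subset=["well_id", "replicate"], keep=False)
    if dup.any():
        raise InputError(
            f"duplicate (well_id, replicate) pairs at rows {plate.index[dup].tolist()}"
        )
    return plate


# ---------------------------------------------------------------------------
# 4PL model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters with the calibrated concentration range."""

    a: float
    b: float
    c: float
    d: float
    valid_range: tuple[float, float]
    residual_summary: dict = field(default_factory=dict)
    response_scale: str = "od"  # "od" or "b_over_b0"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise InputError("inflection concentration c must be positive")
        lo, hi = self.valid_range
        if not lo < hi:
            raise InputError("valid_range low must be below high")

    def __call__(self, x):
        return eval_4pl(x, self.a, self.b, self.c, self.d)


def eval_4pl(x, a: float, b: float, c: float, d: float):
    """Evaluate the 4PL curve; x = 0 maps to the zero-analyte asymptote a."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InputError("concentrations must be non-negative")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    y = np.empty_like(x)
    pos = x > 0
    y[~pos] = a
    y[pos] = d + (a - d) / (1.0 + (x[pos] / c) ** b)
    return float(y[0]) if scalar else y


def fit_4pl(
    concentrations,
    responses,
    response_scale: str = "od",
) -> FourPLFit:
    """Least-squares 4PL fit to (concentration, response) observations.

    Requires at least 4 distinct positive concentration levels.
    Zero-concentration observations are used directly (they pin the
    asymptote ``a``).  Initialization: a = max response, d = min response,
    c = geometric mean of the positive levels, b = 1; c is bounded positive.

    Raises
    ------
    NumericalError
        For flat (non-identifiable) responses or a failed fit.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("concentrations and responses must be equal-length 1-D")
    if np.any(x < 0) or not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise InputError("inputs must be finite and concentrations non-negative")
    levels = np.unique(x[x > 0])
    if levels.size < 4:
        raise InputError(
            f"need >= 4 distinct positive standard levels, got {levels.size}"
        )
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise NumericalError("flat responses: 4PL parameters are not identifiable")

    a0 = float(y.max())
    d0 = float(y.min())
    c0 = float(np.exp(np.mean(np.log(levels))))
    p0 = [a0, 1.0, c0, d0]
    bounds = ([-np.inf, -np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                eval_4pl,
                x,
                y,
                p0=p0,
                bounds=bounds,
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                maxfev=20000,
            )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise NumericalError(f"4PL fit did not converge: {exc}") from exc
    a, b, c, d = (float(v) for v in popt)
    resid = y - eval_4pl(x, a, b, c, d)
    summary = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "max_abs_residual": float(np.abs(resid).max()),
        "n_points": int(x.size),
    }
    fit = FourPLFit(
        a=a,
        b=b,
        c=c,
        d=d,
        valid_range=(float(levels.min()), float(levels.max())),
        residual_summary=summary,
        response_scale=response_scale,
    )
    logger.info(
        "fit_4pl: a=%.4g b=%.4g c=%.4g d=%.4g rmse=%.3g range=%s",
        a,
        b,
        c,
        d,
        summary["rmse"],
        fit.valid_range,
    )
    return fit


def normalize_b_over_b0(responses, b0: float):
    """Normalize responses by the zero-analyte buffer-control response B0."""
    if not np.isfinite(b0) or b0 <= 0:
        raise InputError("B0 must be a positive finite response")
    return np.asarray(responses, dtype=float) / float(b0)


def fit_standard_curve(
    plate: pd.DataFrame,
    response: str = "b_over_b0",
    b0: float | None = None,
) -> tuple[FourPLFit, float | None]:
    """Fit the calibration curve from the standard wells of a plate.

    With ``response="b_over_b0"`` (the default) standard ODs are divided by
    B0 before fitting; B0 is the mean blank OD, or the mean zero-
    concentration standard OD when no blanks exist, unless given
    explicitly.  Returns ``(fit, b0)`` (``b0`` is None on the raw OD
    scale).  A warning is issued when the level means are not monotone
    non-increasing in concentration, which a competitive assay should be.
    """
    validate_plate(plate)
    std = plate[plate["role"] == "standard"].copy()
    if len(std) == 0:
        raise InputError("plate has no standard wells")
    std["concentration"] = pd.to_numeric(std["concentration"])
    if response == "b_over_b0":
        if b0 is None:
            blanks = plate[plate["role"] == "blank"]
            if len(blanks) > 0:
                b0 = float(blanks["od450"].mean())
            else:
                zero = std[std["concentration"] == 0]
                if len(zero) == 0:
                    raise InputError(
                        "B/B0 normalization needs blank wells or zero-"
                        "concentration standards to estimate B0"
                    )
                b0 = float(zero["od450"].mean())
        y = normalize_b_over_b0(std["od450"].to_numpy(), b0)
    elif response == "od":
        b0 = None
        y = std["od450"].to_numpy(dtype=float)
    else:
        raise InputError(f"unknown response scale: {response!r}")

    level_means = (
        std.assign(resp=y).groupby("concentration")["resp"].mean().sort_index()
    )
    if np.any(np.diff(level_means.to_numpy()) > 1e-9):
        warnings.warn(
            "standard responses are not monotone non-increasing in "
            "concentration; competitive-format data expected",
            stacklevel=2,
        )
    fit = fit_4pl(std["concentration"].to_numpy(dtype=float), y, response_scale=response)
    return fit, b0


@dataclass(frozen=True)
class InversionResult:
    """Concentration read off the curve, with censoring at the OD span ends."""

    concentration: float
    censored: str | None = None  # None | "low" | "high"


def invert_4pl(fit: FourPLFit, response: float) -> InversionResult:
    """Invert the fitted curve:  x = c * ((a - d)/(y - d) - 1)^(1/b).

    Responses beyond the zero-analyte asymptote censor low (concentration
    0); responses at or beyond the infinite-analyte asymptote censor high
    (concentration +inf).  Works for decreasing (a > d) curves and,
    symmetrically, increasing ones.
    """
    y = float(response)
    if not np.isfinite(y):
        raise InputError("response must be finite")
    a, b, c, d = fit.a, fit.b, fit.c, fit.d
    if a == d:
        raise NumericalError("degenerate curve: a == d cannot be inverted")
    decreasing = a > d
    lo_asym, hi_asym = (d, a) if decreasing else (a, d)
    if decreasing:
        if y >= a:
            return InversionResult(0.0, None if y == a else "low")
        if y <= d:
            return InversionResult(math.inf, "high")
    else:
        if y <= a:
            return InversionResult(0.0, None if y == a else "low")
        if y >= d:
            return InversionResult(math.inf, "high")
    del lo_asym, hi_asym
    x = c * ((a - d) / (y - d) - 1.0) ** (1.0 / b)
    return InversionResult(float(x), None)


# ---------------------------------------------------------------------------
# Scalar performance formulas
# ---------------------------------------------------------------------------


def inhibition_rate(od_control: float, od_sample: float) -> float:
    """Competitive displacement readout, percent.

    ``(OD_control - OD_sample) / OD_control * 100``; may be negative when
    the sample OD exceeds the control (reported, flagged in the log).
    """
    if od_control <= 0:
        raise InputError("OD_control must be positive")
    rate = (od_control - od_sample) / od_control * 100.0
    if rate < 0:
        logger.warning(
            "negative inhibition rate %.2f%% (OD_sample %.3f > OD_control %.3f)",
            rate,
            od_sample,
            od_control,
        )
    return float(rate)


def pn_series(concentrations, od_positive, negative_control_od: float) -> pd.DataFrame:
    """P/N ratio per concentration: OD_positive / OD_negative."""
    if negative_control_od <= 0:
        raise InputError("negative-control OD must be positive")
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(od_positive, dtype=float)
    if conc.shape != od.shape:
        raise InputError("concentrations and ODs must have equal length")
    return pd.DataFrame(
        {"concentration": conc, "pn": od / float(negative_control_od)}
    ).sort_values("concentration", ignore_index=True)


def min_effective_concentration(
    series: pd.DataFrame, cutoff: float = DEFAULT_PN_CUTOFF
) -> float | None:
    """Lowest tested concentration with P/N strictly above the cutoff."""
    effective = series[series["pn"] > cutoff]
    if len(effective) == 0:
        return None
    return float(effective["concentration"].min())


def lod_loq(blank_concentrations) -> tuple[float, float, float, float, int]:
    """Blank-based detection limits on the concentration scale.

    Returns ``(lod, loq, blank_mean, blank_sd, n_blanks)`` with
    LOD = mean + 3*SD and LOQ = mean + 10*SD, sample SD (n-1 denominator).
    """
    blanks = np.asarray(blank_concentrations, dtype=float)
    if blanks.size < 2:
        raise InputError("need at least 2 blank determinations")
    if not np.all(np.isfinite(blanks)):
        raise InputError("blank concentrations must be finite")
    mean = float(blanks.mean())
    sd = float(blanks.std(ddof=1))
    if sd == 0:
        warnings.warn("degenerate blank SD = 0: LOD equals LOQ", stacklevel=2)
    return mean + 3.0 * sd, mean + 10.0 * sd, mean, sd, int(blanks.size)


def convert_to_food(
    conc_solution: float, dilution_factor: float = DEFAULT_DILUTION_FACTOR
) -> float:
    """µg/mL in extract -> mg/kg food for a 1 g : k mL extraction.

    Unit algebra: µg/mL * (mL buffer per g sample) = µg/g = mg/kg.
    """
    if dilution_factor <= 0:
        raise InputError("dilution factor must be positive")
    return conc_solution * dilution_factor


def milk_protein_equivalent(
    conc_food: float, blg_fraction: float = DEFAULT_BLG_FRACTION
) -> float:
    """mg β-lactoglobulin per kg food -> mg milk protein per kg food."""
    if not 0 < blg_fraction <= 1:
        raise InputError("blg_fraction must be in (0, 1]")
    return conc_food / blg_fraction


def recovery(measured: float, spiked: float) -> float:
    """Measured over spiked concentration, percent."""
    if spiked <= 0:
        raise InputError("spiked level must be positive")
    return measured / spiked * 100.0


@dataclass(frozen=True)
class DetectionLimits:
    """LOD/LOQ on the solution, food and milk-protein-equivalent scales."""

    lod_solution: float
    loq_solution: float
    lod_food: float
    loq_food: float
    lod_milk_protein: float
    loq_milk_protein: float
    blank_mean: float
    blank_sd: float
    n_blanks: int
    dilution_factor: float = DEFAULT_DILUTION_FACTOR
    blg_fraction: float = DEFAULT_BLG_FRACTION


def detection_limits(
    blank_concentrations,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    blg_fraction: float = DEFAULT_BLG_FRACTION,
) -> DetectionLimits:
    """LOD/LOQ from blank concentration estimates, on all three scales."""
    lod, loq, mean, sd, n = lod_loq(blank_concentrations)
    lod_food = convert_to_food(lod, dilution_factor)
    loq_food = convert_to_food(loq, dilution_factor)
    return DetectionLimits(
        lod_solution=lod,
        loq_solution=loq,
        lod_food=lod_food,
        loq_food=loq_food,
        lod_milk_protein=milk_protein_equivalent(lod_food, blg_fraction),
        loq_milk_protein=milk_protein_equivalent(loq_food, blg_fraction),
        blank_mean=mean,
        blank_sd=sd,
        n_blanks=n,
        dilution_factor=dilution_factor,
        blg_fraction=blg_fraction,
    )


@dataclass(frozen=True)
class PrecisionPanel:
    """Intra-/inter-assay repeatability summary (CVs in percent)."""

    intra_mean: float
    intra_sd: float
    intra_cv: float
    inter_mean: float
    inter_sd: float
    inter_cv: float
    day_means: tuple[float, ...]
    n_intra: int
    n_inter: int


def _cv_percent(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if mean == 0:
        raise NumericalError("CV undefined for zero mean")
    return mean, sd, sd / mean * 100.0


def precision_panel(intra_values, inter_values_by_day) -> PrecisionPanel:
    """Intra-assay CV over one run; inter-assay CV over all cross-day values.

    ``intra_values``: replicate estimates from a single run (the validation
    design uses 25).  ``inter_values_by_day``: iterable of per-day estimate
    lists (the design uses 5 estimates on each of 5 days).  Day means are
    reported alongside the full-data inter-assay CV.
    """
    intra = np.asarray(intra_values, dtype=float)
    days = [np.asarray(day, dtype=float) for day in inter_values_by_day]
    if intra.size < 2:
        raise InputError("need >= 2 intra-assay replicates")
    if len(days) < 2 or any(day.size < 1 for day in days):
        raise InputError("need >= 2 days with >= 1 estimate each")
    inter = np.concatenate(days)
    if inter.size < 2:
        raise InputError("need >= 2 inter-assay values")
    i_mean, i_sd, i_cv = _cv_percent(intra)
    e_mean, e_sd, e_cv = _cv_percent(inter)
    return PrecisionPanel(
        intra_mean=i_mean,
        intra_sd=i_sd,
        intra_cv=i_cv,
        inter_mean=e_mean,
        inter_sd=e_sd,
        inter_cv=e_cv,
        day_means=tuple(float(day.mean()) for day in days),
        n_intra=int(intra.size),
        n_inter=int(inter.size),
    )


# ---------------------------------------------------------------------------
# Censored reporting and the plate-level pipeline
# ---------------------------------------------------------------------------


def censor_and_report(results: pd.DataFrame, limits: DetectionLimits) -> pd.DataFrame:
    """Apply <LOD / <LOQ censoring to per-sample solution concentrations.

    Values below LOD report "<LOD"; at or above LOD but below LOQ report
    "<LOQ"; values at or above LOQ report numerically (a value exactly at
    the LOQ counts as quantifiable).  Expects a ``concentration_solution``
    column; adds ``censoring`` and ``display`` columns.
    """
    if "concentration_solution" not in results.columns:
        raise InputError("results need a concentration_solution column")
    out = results.copy()
    conc = out["concentration_solution"].to_numpy(dtype=float)
    censoring = np.where(
        conc < limits.lod_solution,
        "below_lod",
        np.where(conc < limits.loq_solution, "below_loq", "quantified"),
    )
    display = []
    for value, flag in zip(conc, censoring):
        if flag == "below_lod":
            display.append("<LOD")
        elif flag == "below_loq":
            display.append("<LOQ")
        else:
            food = value * limits.dilution_factor
            display.append(f"{food:.2f}")
    out["censoring"] = censoring
    out["display_food_mg_per_kg"] = display
    return out


@dataclass(frozen=True)
class AssayAnalysis:
    """Everything derived from one plate: curve, limits, samples, P/N."""

    fit: FourPLFit
    b0: float | None
    limits: DetectionLimits | None
    samples: pd.DataFrame
    pn: pd.DataFrame | None
    min_effective: float | None


def _invert_for_blank(fit: FourPLFit, response: float) -> float:
    """Blank inversion with the zero floor: censored-low reads become 0."""
    result = invert_4pl(fit, response)
    if result.censored == "low":
        logger.info(
            "blank response %.4f above the zero-analyte asymptote; floored to 0",
            response,
        )
        return 0.0
    if result.censored == "high":  # pragma: no cover - pathological blank
        raise NumericalError("blank response at the infinite-analyte asymptote")
    return result.concentration


def analyze_plate(
    plate: pd.DataFrame,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    blg_fraction: float = DEFAULT_BLG_FRACTION,
    pn_cutoff: float = DEFAULT_PN_CUTOFF,
    response: str = "b_over_b0",
) -> AssayAnalysis:
    """Full calibration + quantification analysis of one plate table.

    Stages: fit the standard curve (B/B0 by default), invert blank wells for
    LOD/LOQ, invert sample replicates for concentrations (solution and food
    scales), censor against the limits, and compute the P/N series against
    negative-control wells when present.
    """
    plate = validate_plate(plate)
    fit, b0 = fit_standard_curve(plate, response=response)

    def to_response(od: np.ndarray) -> np.ndarray:
        return normalize_b_over_b0(od, b0) if b0 is not None else od

    blanks = plate[plate["role"] == "blank"]
    limits = None
    if len(blanks) >= 2:
        blank_conc = [
            _invert_for_blank(fit, r) for r in to_response(blanks["od450"].to_numpy())
        ]
        limits = detection_limits(blank_conc, dilution_factor, blg_fraction)

    sample_rows = []
    samples = plate[plate["role"] == "sample"]
    for well_id, group in samples.groupby("well_id", sort=True):
        responses = to_response(group["od450"].to_numpy())
        concs = []
        for r in responses:
            result = invert_4pl(fit, r)
            concs.append(0.0 if result.censored == "low" else result.concentration)
        concs = np.asarray(concs, dtype=float)
        mean = float(concs.mean())
        sd = float(concs.std(ddof=1)) if concs.size > 1 else float("nan")
        sample_rows.append(
            {
                "sample_id": well_id,
                "n_replicates": int(concs.size),
                "concentration_solution": mean,
                "solution_sd": sd,
                "concentration_food": convert_to_food(mean, dilution_factor),
                "milk_protein_equivalent": milk_protein_equivalent(
                    convert_to_food(mean, dilution_factor), blg_fraction
                ),
            }
        )
    sample_table = pd.DataFrame(
        sample_rows,
        columns=[
            "sample_id",
            "n_replicates",
            "concentration_solution",
            "solution_sd",
            "concentration_food",
            "milk_protein_equivalent",
        ],
    )
    if limits is not None and len(sample_table) > 0:
        sample_table = censor_and_report(sample_table, limits)

    pn = None
    min_effective = None
    negatives = plate[plate["role"] == "negative_control"]
    std = plate[plate["role"] == "standard"]
    if len(negatives) > 0 and len(std) > 0:
        neg_od = float(negatives["od450"].mean())
        level_od = std.groupby(pd.to_numeric(std["concentration"]))["od450"].mean()
        pn = pn_series(level_od.index.to_numpy(), level_od.to_numpy(), neg_od)
        min_effective = min_effective_concentration(pn, pn_cutoff)

    return AssayAnalysis(
        fit=fit,
        b0=b0,
        limits=limits,
        samples=sample_table,
        pn=pn,
        min_effective=min_effective,
    )


def plot_standard_curve(fit: FourPLFit, plate: pd.DataFrame | None, path) -> None:
    """Write a log-x standard-curve figure (optional diagnostic output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = fit.valid_range
    grid = np.geomspace(lo / 2, hi * 2, 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(grid, fit(grid), "-", color="tab:blue", label="4PL fit")
    if plate is not None:
        std = plate[plate["role"] == "standard"]
        conc = pd.to_numeric(std["concentration"])
        mask = (conc > 0).to_numpy()
        ax.plot(conc.to_numpy()[mask], std["od450"].to_numpy()[mask], "o",
                color="k", ms=4, label="standards (OD450)")
    ax.set_xscale("log")
    ax.set_xlabel("β-lactoglobulin (µg/mL)")
    ax.set_ylabel(fit.response_scale)
    ax.axvspan(lo, hi, color="tab:blue", alpha=0.08, label="calibrated range")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
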