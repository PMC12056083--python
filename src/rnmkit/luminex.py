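"""Multiplex-immunoassay (Luminex) secretome calibration.

Raw bead-based immunoassay readouts (median fluorescence intensity, MFI)
are turned into the [0, 1]-normalized, reference-subtracted condition
vectors that the model-experiment concordance consumes:

1. blank subtraction (net MFI, floored at 0);
2. per-analyte 5-parameter-logistic (5PL) standard-curve fit and
   closed-form inversion to concentration, with censoring at the curve
   asymptotes;
3. linear normalization of concentration between the lower and upper
   limits of quantification (LOQ) to x in [0, 1];
4. aggregation across donors (median) and days (median pooling by
   default), then subtraction of the reference condition
   (control unloaded) giving x' in [-1, 1].

The 5PL standard curve is parameterized as

    MFI(c) = L + (U - L) / (1 + (C / c)^B)^G

with lower/upper asymptotes L < U, inflection C > 0, slope B > 0 and
asymmetry G > 0; G = 1 reduces to the 4PL.  The curve is strictly
increasing in concentration, so inversion is closed-form between the
asymptotes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SecretomePanel",
    "StandardCurve5PL",
    "CalibratedSecretome",
    "CalibrationError",
    "REFERENCE_CONDITION",
    "subtract_blank",
    "fit_5pl",
    "invert_5pl",
    "normalize_loq",
    "calibrate_panel",
    "aggregate_and_reference",
]

REFERENCE_CONDITION = "control_unloaded"

MEASUREMENT_COLS = ["analyte", "donor", "condition", "day", "mfi"]


class CalibrationError(ValueError):
    """Raised for structurally invalid panels or calibration configs."""


@dataclass
class SecretomePanel:
    """Raw multiplex panel: measurements plus standards, blanks and LOQs.

    All four tables are pandas DataFrames in the documented CSV dialects:

    * ``measurements``: analyte, donor, condition, day, mfi
    * ``standards``:    analyte, concentration, mfi
    * ``blanks``:       analyte, mfi
    * ``loq``:          analyte, lloq, uloq
    """

    measurements: pd.DataFrame
    standards: pd.DataFrame
    blanks: pd.DataFrame
    loq: pd.DataFrame
    blank_subtracted: bool = False

    def __post_init__(self) -> None:
        for name, df, cols in [
            ("measurements", self.measurements, MEASUREMENT_COLS),
            ("standards", self.standards, ["analyte", "concentration", "mfi"]),
            ("blanks", self.blanks, ["analyte", "mfi"]),
            ("loq", self.loq, ["analyte", "lloq", "uloq"]),
        ]:
            missing = set(cols) - set(df.columns)
            if missing:
                raise CalibrationError(f"{name} table missing columns {sorted(missing)}")
        bad = self.loq[self.loq["lloq"] >= self.loq["uloq"]]
        if len(bad):
            raise CalibrationError(
                f"lloq must be < uloq; violated for {bad['analyte'].tolist()}"
            )
        counts = self.standards.groupby("analyte")["concentration"].nunique()
        thin = counts[counts < 4]
        if len(thin):
            raise CalibrationError(
                f"standards must span >= 4 concentrations; violated for "
                f"{thin.index.tolist()}"
            )

    @property
    def analytes(self) -> list[str]:
        return sorted(self.measurements["analyte"].unique())

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv_dir(cls, directory: str | Path) -> "SecretomePanel":
        d = Path(directory)
        return cls(
            measurements=pd.read_csv(d / "measurements.csv"),
            standards=pd.read_csv(d / "standards.csv"),
            blanks=pd.read_csv(d / "blanks.csv"),
            loq=pd.read_csv(d / "loq.csv"),
        )

    def to_csv_dir(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(d / "measurements.csv", index=False)
        self.standards.to_csv(d / "standards.csv", index=False)
        self.blanks.to_csv(d / "blanks.csv", index=False)
        self.loq.to_csv(d / "loq.csv", index=False)


def subtract_blank(panel: SecretomePanel) -> SecretomePanel:
    """Replace measurement and standard MFIs by net MFI (value − blank).

    Net values are floored at 0; floored rows are flagged in a
    ``floored`` column.  A missing blank for a measured analyte is an
    error naming the analyte.
    """
    blanks = panel.blanks.set_index("analyte")["mfi"]
    analytes = set(panel.measurements["analyte"]) | set(panel.standards["analyte"])
    missing = sorted(analytes - set(blanks.index))
    if missing:
        raise CalibrationError(f"no blank for analytes: {missing}")

    def _net(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        raw = out["mfi"] - out["analyte"].map(blanks)
        out["floored"] = raw < 0
        out["mfi"] = raw.clip(lower=0.0)
        return out

    return SecretomePanel(
        measurements=_net(panel.measurements),
        standards=_net(panel.standards),
        blanks=panel.blanks,
        loq=panel.loq,
        blank_subtracted=True,
    )


@dataclass(frozen=True)
class StandardCurve5PL:
    """Fitted 5PL standard curve with diagnostics."""

    lower: float  # L, asymptote as c -> 0
    upper: float  # U, asymptote as c -> inf
    inflection: float  # C
    slope: float  # B
    asymmetry: float  # G (1 for the 4PL fallback)
    residual_norm: float = float("nan")
    converged: bool = True
    is_4pl_fallback: bool = False

    def __post_init__(self) -> None:
        if self.converged and not self.upper > self.lower:
            raise CalibrationError("upper asymptote must exceed lower asymptote")

    def predict(self, concentration: np.ndarray | float) -> np.ndarray | float:
        return _five_pl(
            np.asarray(concentration, dtype=float),
            self.lower,
            self.upper,
            self.inflection,
            self.slope,
            self.asymmetry,
        )


def _five_pl(c, lower, upper, inflection, slope, asymmetry):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, inflection / np.maximum(c, 1e-300), np.inf)
    return lower + (upper - lower) / (1.0 + ratio**slope) ** asymmetry


def _initial_guess(conc: np.ndarray, mfi: np.ndarray) -> list[float]:
    lo = float(mfi.min())
    hi = float(mfi.max())
    span = max(hi - lo, 1e-9)
    mid_mfi = lo + 0.5 * span
    infl = float(conc[np.argmin(np.abs(mfi - mid_mfi))])
    return [max(lo - 0.05 * span, 0.0), hi + 0.05 * span, max(infl, 1e-9), 1.0, 1.0]


def fit_5pl(
    standards: Sequence[tuple[float, float]] | pd.DataFrame,
) -> StandardCurve5PL:
    """Least-squares 5PL fit of (concentration, MFI) standards.

    Residuals are weighted by 1/MFI (constant-CV weighting, the standard
    choice for immunoassay standard curves whose error is multiplicative),
    which keeps the inflection identifiable against the asymmetry
    parameter.  With fewer than 5 distinct concentrations the asymmetry
    is unidentifiable anyway and the fit falls back to a 4PL (asymmetry
    fixed at 1), flagged via ``is_4pl_fallback``.  Optimizer failure
    yields a curve with ``converged=False`` instead of raising; such
    analytes are excluded downstream with a warning.
    """
    if isinstance(standards, pd.DataFrame):
        conc = standards["concentration"].to_numpy(dtype=float)
        mfi = standards["mfi"].to_numpy(dtype=float)
    else:
        arr = np.asarray(standards, dtype=float)
        conc, mfi = arr[:, 0], arr[:, 1]
    order = np.argsort(conc)
    conc, mfi = conc[order], mfi[order]
    n_distinct = len(np.unique(conc))
    if n_distinct < 4:
        raise CalibrationError(
            f"need >= 4 distinct standard concentrations, got {n_distinct}"
        )
    fallback = n_distinct < 5
    p0 = _initial_guess(conc, mfi)
    span = max(mfi.max() - mfi.min(), 1e-9)
    lower_bounds = [0.0, mfi.min() - 0.5 * span, 1e-12, 1e-3, 1e-3]
    upper_bounds = [mfi.min() + 0.5 * span, mfi.max() + 10 * span, conc.max() * 1e3, 50.0, 50.0]

    if fallback:
        def model(c, L, U, C, B):
            return _five_pl(c, L, U, C, B, 1.0)
        p0_use = p0[:4]
        bounds = (lower_bounds[:4], upper_bounds[:4])
    else:
        model = _five_pl
        p0_use = p0
        bounds = (lower_bounds, upper_bounds)

    # constant-CV weights, floored so near-zero net MFIs cannot dominate
    sigma = np.maximum(mfi, 0.01 * mfi.max()) if mfi.max() > 0 else None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                conc,
                mfi,
                p0=p0_use,
                bounds=bounds,
                sigma=sigma,
                maxfev=50_000,
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
            )
    except (RuntimeError, ValueError):
        return StandardCurve5PL(
            lower=float("nan"),
            upper=float("nan"),
            inflection=float("nan"),
            slope=float("nan"),
            asymmetry=float("nan"),
            residual_norm=float("inf"),
            converged=False,
            is_4pl_fallback=fallback,
        )
    if fallback:
        popt = np.append(popt, 1.0)
    residual = float(np.linalg.norm(mfi - _five_pl(conc, *popt)))
    return StandardCurve5PL(
        lower=float(popt[0]),
        upper=float(popt[1]),
        inflection=float(popt[2]),
        slope=float(popt[3]),
        asymmetry=float(popt[4]),
        residual_norm=residual,
        converged=True,
        is_4pl_fallback=fallback,
    )


def invert_5pl(
    curve: StandardCurve5PL,
    net_mfi: float,
    lloq: float,
    uloq: float,
) -> tuple[float, str]:
    """Closed-form inversion of a fitted curve to concentration.

    Returns ``(concentration, censor)``.  Readings outside the
    quantifiable range are censored at the LOQ limits: an MFI at/below
    the lower asymptote, or whose inverted concentration falls at/below
    the lower LOQ, reports the lower LOQ with ``censor="lower"``
    (symmetrically for the upper side), so the reported concentration is
    non-decreasing in MFI.
    """
    if not curve.converged:
        raise CalibrationError("cannot invert a non-converged curve")
    if net_mfi <= curve.lower:
        return lloq, "lower"
    if net_mfi >= curve.upper:
        return uloq, "upper"
    frac = (curve.upper - curve.lower) / (net_mfi - curve.lower)
    inner = frac ** (1.0 / curve.asymmetry) - 1.0
    conc = float(curve.inflection * inner ** (-1.0 / curve.slope))
    if conc <= lloq:
        return lloq, "lower"
    if conc >= uloq:
        return uloq, "upper"
    return conc, "none"


def normalize_loq(concentration: float, lloq: float, uloq: float) -> float:
    """Linear LOQ normalization: lower LOQ maps to 0, upper LOQ to 1,
    clipped outside."""
    if lloq >= uloq:
        raise CalibrationError(f"lloq ({lloq}) must be < uloq ({uloq})")
    return float(np.clip((concentration - lloq) / (uloq - lloq), 0.0, 1.0))


def calibrate_panel(
    panel: SecretomePanel,
    log_scale: bool = False,
) -> tuple[pd.DataFrame, dict[str, StandardCurve5PL], list[str]]:
    """Run blank subtraction, 5PL calibration and LOQ normalization.

    Returns ``(calibrated, curves, excluded)`` where ``calibrated`` has
    one row per measurement with ``concentration``, normalized ``x`` and
    a ``censor`` flag, ``curves`` maps analyte to fitted curve, and
    ``excluded`` lists analytes dropped for non-converged fits.

    ``log_scale=True`` normalizes log10-concentration between the
    log10-LOQ limits instead of the default linear scale.
    """
    if not panel.blank_subtracted:
        panel = subtract_blank(panel)
    loq = panel.loq.set_index("analyte")
    curves: dict[str, StandardCurve5PL] = {}
    excluded: list[str] = []
    rows = []
    for analyte, std in panel.standards.groupby("analyte"):
        curves[analyte] = fit_5pl(std)
        if not curves[analyte].converged:
            excluded.append(analyte)
            warnings.warn(
                f"5PL fit failed for {analyte!r}; analyte excluded", stacklevel=2
            )
    for rec in panel.measurements.itertuples(index=False):
        if rec.analyte in excluded or rec.analyte not in curves:
            continue
        lloq = float(loq.loc[rec.analyte, "lloq"])
        uloq = float(loq.loc[rec.analyte, "uloq"])
        conc, censor = invert_5pl(curves[rec.analyte], rec.mfi, lloq, uloq)
        if log_scale:
            x = normalize_loq(np.log10(max(conc, 1e-300)), np.log10(lloq), np.log10(uloq))
        else:
            x = normalize_loq(conc, lloq, uloq)
        rows.append(
            {
                "analyte": rec.analyte,
                "donor": rec.donor,
                "condition": rec.condition,
                "day": rec.day,
                "concentration": conc,
                "x": x,
                "censor": censor,
            }
        )
    calibrated = pd.DataFrame(
        rows,
        columns=["analyte", "donor", "condition", "day", "concentration", "x", "censor"],
    )
    return calibrated, curves, excluded


@dataclass
class CalibratedSecretome:
    """Condition-level calibrated secretome ready for concordance.

    ``table`` has one row per (analyte, condition[, day]) with the donor
    medians: ``concentration``, normalized ``x`` in [0, 1], the
    reference-subtracted ``x_ref`` in [-1, 1] and censoring fractions.
    """

    table: pd.DataFrame
    reference: str = REFERENCE_CONDITION
    per_day: bool = False
    excluded: list[str] = field(default_factory=list)

    def vector(self, condition: str, day: int | None = None) -> pd.Series:
        """Referenced values x' for one condition, indexed by analyte."""
        sub = self.table[self.table["condition"] == condition]
        if self.per_day:
            if day is None:
                raise CalibrationError("per-day secretome requires a day argument")
            sub = sub[sub["day"] == day]
        return sub.set_index("analyte")["x_ref"]

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def aggregate_and_reference(
    calibrated: pd.DataFrame,
    reference: str = REFERENCE_CONDITION,
    per_day: bool = False,
    excluded: Sequence[str] = (),
) -> CalibratedSecretome:
    """Median-aggregate calibrated values and subtract the reference.

    Donor replicates are reduced by the median; unless ``per_day`` is
    set, day 7 and day 14 values are then pooled by median into a single
    value per condition (the network model carries no time axis).  The
    reference condition's x is subtracted per analyte, giving
    x' in [-1, 1] with the reference itself exactly 0.  Analytes lacking
    a reference cell are excluded with a warning.
    """
    if reference not in set(calibrated["condition"]):
        raise CalibrationError(
            f"reference condition {reference!r} absent from calibrated data"
        )
    keys = ["analyte", "condition", "day"] if per_day else ["analyte", "condition"]
    grouped = (
        calibrated.groupby(keys)
        .agg(
            concentration=("concentration", "median"),
            x=("x", "median"),
            frac_lower_censored=("censor", lambda s: float(np.mean(s == "lower"))),
            frac_upper_censored=("censor", lambda s: float(np.mean(s == "upper"))),
        )
        .reset_index()
    )
    if per_day:
        ref = grouped[grouped["condition"] == reference].set_index(["analyte", "day"])["x"]
        idx = pd.MultiIndex.from_frame(grouped[["analyte", "day"]])
    else:
        ref = grouped[grouped["condition"] == reference].set_index("analyte")["x"]
        idx = pd.Index(grouped["analyte"])
    ref_vals = ref.reindex(idx).to_numpy()
    missing_ref = sorted(grouped.loc[np.isnan(ref_vals), "analyte"].unique())
    if missing_ref:
        warnings.warn(
            f"analytes without reference cell excluded: {missing_ref}", stacklevel=2
        )
    grouped["x_ref"] = grouped["x"].to_numpy() - ref_vals
    grouped = grouped[~np.isnan(grouped["x_ref"])].reset_index(drop=True)
    return CalibratedSecretome(
        table=grouped,
        reference=reference,
        per_day=per_day,
        excluded=sorted(set(excluded) | set(missing_ref)),
    )
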