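"""Plate-assay calculators: linear standard curves, α-amylase inhibition,
and Griess nitrite quantification.

The α-amylase inhibition percentage follows the classical
reducing-sugar-release formulation: after converting absorbances to maltose
equivalents via a standard curve,

    inhibition (%) = 100 − 100 · (maltose_sample − maltose_blank) / maltose_negative_control

so a sample releasing no maltose above blank scores 100 % inhibition and a
sample releasing as much as the uninhibited enzyme control scores 0 %.
Nitrite is quantified by inverting a NaNO₂ standard curve (typically fitted
over 3.125–100 µM); values outside the fitted range are flagged as
extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, Tuple

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: signal = slope · concentration + intercept."""

    slope: float
    intercept: float
    concentration_unit: str = ""
    fit_range: Tuple[float, float] = (0.0, 0.0)
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard curve slope must be non-zero")

    def evaluate(self, concentration: float) -> float:
        """Predicted signal at a concentration."""
        return self.slope * concentration + self.intercept

    def invert(self, signal: float) -> float:
        """Concentration producing the given signal."""
        return (signal - self.intercept) / self.slope


def fit_standard_curve(points: Sequence[Tuple[float, float]],
                       concentration_unit: str = "") -> StandardCurve:
    """Ordinary least-squares line through (concentration, signal) points.

    Replicate signals at the same concentration are averaged before fitting.
    Requires at least two distinct concentrations.
    """
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    df = pd.DataFrame(points, columns=["concentration", "signal"])
    means = df.groupby("concentration", sort=True)["signal"].mean().reset_index()
    if len(means) < 2:
        raise ValueError("calibration requires at least two distinct concentrations")
    res = stats.linregress(means["concentration"], means["signal"])
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        concentration_unit=concentration_unit,
        fit_range=(float(means["concentration"].min()), float(means["concentration"].max())),
        r_squared=float(res.rvalue) ** 2,
    )


@dataclass(frozen=True)
class InhibitionReading:
    """Maltose equivalents (mg) for one inhibition measurement."""

    maltose_sample: float
    maltose_blank: float
    maltose_negative_control: float

    def __post_init__(self) -> None:
        if self.maltose_negative_control <= 0:
            raise ValueError("negative control maltose must be positive")


def inhibition_percent(r: InhibitionReading) -> float:
    """α-amylase inhibition (%), to 1 decimal; may be negative (activation)
    or exceed 100."""
    value = 100.0 - 100.0 * (r.maltose_sample - r.maltose_blank) / r.maltose_negative_control
    return round(value, 1)


class NitriteResult(NamedTuple):
    concentration: float
    extrapolated: bool


def nitrite_concentration(signal: float, curve: StandardCurve) -> NitriteResult:
    """Invert a NaNO₂ standard curve; flag values outside the fitted range."""
    conc = curve.invert(signal)
    lo, hi = curve.fit_range
    return NitriteResult(conc, not (lo <= conc <= hi))


def read_plate_tsv(path) -> pd.DataFrame:
    """Read a plate table: columns well, role (sample / blank /
    negative_control / standard), concentration, absorbance."""
    df = pd.read_csv(path, sep="\t")
    required = {"well", "role", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    return df


def amylase_inhibition_report(plate: pd.DataFrame) -> pd.DataFrame:
    """Full plate workflow: fit the maltose curve from standard wells, convert
    absorbances to maltose equivalents, and report % inhibition per sample.

    Sample wells sharing a ``well`` label are replicate-averaged (means enter
    the formula). Returns a DataFrame with columns well, maltose_mg,
    inhibition_pct.
    """
    standards = plate[plate["role"] == "standard"]
    if standards.empty:
        raise ValueError("no standard wells in plate")
    curve = fit_standard_curve(
        list(zip(standards["concentration"], standards["absorbance"])),
        concentration_unit="mg maltose",
    )

    def maltose(group: pd.DataFrame) -> float:
        return float(group["absorbance"].map(curve.invert).mean())

    blank = maltose(plate[plate["role"] == "blank"])
    control = maltose(plate[plate["role"] == "negative_control"])
    rows = []
    for well, group in plate[plate["role"] == "sample"].groupby("well", sort=False):
        m = maltose(group)
        pct = inhibition_percent(InhibitionReading(m, blank, control))
        rows.append({"well": well, "maltose_mg": round(m, 4), "inhibition_pct": pct})
    return pd.DataFrame(rows)
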