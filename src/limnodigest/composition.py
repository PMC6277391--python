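"""Biomass mass balance and compositional fractionation.

The feeding mass balance compares the wood a batch of animals ingested with
the fecal pellets they produced: mass loss during gut passage is the ingested
mass not recovered as feces, expressed as a percentage of ingested mass.
Compositional analysis splits wood and feces into three operational fractions
-- acetyl-bromide-soluble lignin (ABSL), TFA-soluble hemicellulose, and
H2SO4-soluble cellulose -- plus per-sugar amounts from HPAEC calibration.
Fecal fraction percentages are rescaled so they total (100 - mass loss),
putting wood and feces on a common ingested-mass basis before computing
per-fraction digestion deltas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FRACTIONS",
    "SUGARS",
    "FeedingRecord",
    "AbslMeasurement",
    "BiomassSample",
    "HPAECCalibration",
    "mass_loss_percent",
    "mass_loss_summary",
    "absl_percent",
    "fraction_percentages",
    "normalize_feces_to_mass_loss",
    "as_percentages",
    "normalize_sample_to_mass_loss",
    "fit_calibration",
    "quantify_sugars",
    "digestion_delta",
]

FRACTIONS = ("lignin", "hemicellulose", "cellulose")
#: the nine monosaccharides of the calibration standard mixture
SUGARS = ("Fuc", "Ara", "Rha", "Gal", "Glu", "Xyl", "Man", "GalA", "GlcA")
#: default acetyl-bromide-soluble-lignin extinction coefficient (poplar), L/(g cm)
ABSL_COEFFICIENT = 18.21


@dataclass(frozen=True)
class FeedingRecord:
    """Masses (mg) for one feeding batch: initial and remaining wood, feces."""

    batch: str
    initial_mg: float
    remaining_mg: float
    feces_mg: float

    def __post_init__(self):
        if min(self.initial_mg, self.remaining_mg, self.feces_mg) < 0:
            raise ValueError("masses must be non-negative")
        if self.remaining_mg > self.initial_mg:
            raise ValueError("remaining wood cannot exceed initial wood")

    @property
    def ingested_mg(self) -> float:
        return self.initial_mg - self.remaining_mg


def mass_loss_percent(rec: FeedingRecord) -> float:
    """Percent of ingested mass lost during gut passage.

    100 * (ingested - feces) / ingested.  Negative values (feces heavier than
    ingested wood, possible under measurement noise) are returned as-is, never
    clipped.
    """
    ingested = rec.ingested_mg
    if ingested <= 0:
        raise ValueError(f"batch {rec.batch}: no wood was ingested")
    return 100.0 * (ingested - rec.feces_mg) / ingested


def mass_loss_summary(
    records: list[FeedingRecord], method: str = "per_batch"
) -> tuple[float, float]:
    """(mean, SD) of mass loss over batches.

    ``per_batch`` averages the per-batch loss percentages (the default,
    matching per-sample mean +/- SD reporting); ``pooled`` forms the ratio of
    summed masses across batches (SD 0 by construction).
    """
    if not records:
        raise ValueError("no feeding records")
    if method == "per_batch":
        losses = [mass_loss_percent(r) for r in records]
        return float(np.mean(losses)), float(np.std(losses, ddof=1)) if len(losses) > 1 else 0.0
    if method == "pooled":
        ingested = sum(r.ingested_mg for r in records)
        feces = sum(r.feces_mg for r in records)
        if ingested <= 0:
            raise ValueError("no wood was ingested in any batch")
        return 100.0 * (ingested - feces) / ingested, 0.0
    raise ValueError("method must be 'per_batch' or 'pooled'")


@dataclass(frozen=True)
class AbslMeasurement:
    """One acetyl-bromide-soluble lignin absorbance measurement.

    Units: absorbance at 280 nm (dimensionless), extinction coefficient in
    L g^-1 cm^-1, path length cm, total volume mL, biomass weight mg.
    """

    absorbance: float
    biomass_weight_mg: float
    total_volume_ml: float = 5.0
    dilution: float = 10.0
    coefficient: float = ABSL_COEFFICIENT
    path_length_cm: float = 1.0

    def __post_init__(self):
        if self.absorbance < 0:
            raise ValueError("absorbance must be non-negative")
        for name in ("biomass_weight_mg", "total_volume_ml", "dilution",
                     "coefficient", "path_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def absl_percent(m: AbslMeasurement) -> float:
    """Percent lignin by the ABSL formula.

    %ABSL = (A / (coefficient * path)) * (total volume * 100% / weight) * dilution,
    with volume in mL and weight in mg (so mL/mg * L g^-1 cancels to %).
    """
    return (
        (m.absorbance / (m.coefficient * m.path_length_cm))
        * (m.total_volume_ml * 100.0 / m.biomass_weight_mg)
        * m.dilution
    )


@dataclass
class BiomassSample:
    """Per-sample masses of the three fractions and per-sugar amounts.

    ``fractions`` maps fraction name -> mass; ``sugars`` maps fraction name
    ("hemicellulose" for the TFA extract, "cellulose" for the H2SO4 extract)
    -> sugar -> amount, in the same units as the fraction masses.
    """

    sample_id: str
    fractions: dict[str, float]
    sugars: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(FRACTIONS) - set(self.fractions)
        if missing:
            raise ValueError(f"sample {self.sample_id}: missing fractions {sorted(missing)}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError(f"sample {self.sample_id}: negative fraction mass")
        for frac, sugar_map in self.sugars.items():
            if any(v < 0 for v in sugar_map.values()):
                raise ValueError(f"sample {self.sample_id}: negative sugar amount in {frac}")

    @property
    def total(self) -> float:
        return sum(self.fractions[f] for f in FRACTIONS)


def fraction_percentages(sample: BiomassSample) -> dict[str, float]:
    """Each fraction as percent of the three-fraction total (sums to 100)."""
    total = sample.total
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id}: total fraction mass is zero")
    return {f: 100.0 * sample.fractions[f] / total for f in FRACTIONS}


def normalize_feces_to_mass_loss(
    percentages: dict[str, float], mass_loss_pct: float
) -> dict[str, float]:
    """Rescale fecal fraction percentages to total (100 - mass loss).

    With the study's 22% mass loss the fecal fractions sum to 78, putting them
    on the same ingested-mass basis as the wood fractions.
    """
    if not 0.0 <= mass_loss_pct <= 100.0:
        raise ValueError("mass loss percent must be in [0, 100]")
    total = sum(percentages.values())
    if not math.isclose(total, 100.0, abs_tol=1e-6):
        raise ValueError(f"input percentages must sum to 100 (got {total})")
    scale = (100.0 - mass_loss_pct) / 100.0
    return {k: v * scale for k, v in percentages.items()}


def as_percentages(sample: BiomassSample) -> BiomassSample:
    """Re-express a sample's fractions (and sugars) as percent of its total."""
    total = sample.total
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id}: total fraction mass is zero")
    scale = 100.0 / total
    return BiomassSample(
        sample_id=sample.sample_id,
        fractions={k: v * scale for k, v in sample.fractions.items()},
        sugars={
            frac: {s: v * scale for s, v in sugar_map.items()}
            for frac, sugar_map in sample.sugars.items()
        },
    )


def normalize_sample_to_mass_loss(
    sample_pct: BiomassSample, mass_loss_pct: float
) -> BiomassSample:
    """Apply the fecal (100 - loss)% rescaling to a percentage-basis sample."""
    scaled = normalize_feces_to_mass_loss(
        {f: sample_pct.fractions[f] for f in FRACTIONS}, mass_loss_pct
    )
    factor = (100.0 - mass_loss_pct) / 100.0
    return BiomassSample(
        sample_id=sample_pct.sample_id,
        fractions=scaled,
        sugars={
            frac: {s: v * factor for s, v in sugar_map.items()}
            for frac, sugar_map in sample_pct.sugars.items()
        },
    )


@dataclass(frozen=True)
class HPAECCalibration:
    """Per-analyte linear calibration area = slope * amount + intercept."""

    slopes: dict[str, float]
    intercepts: dict[str, float]

    def __post_init__(self):
        for analyte, slope in self.slopes.items():
            if slope <= 0:
                raise ValueError(f"calibration slope for {analyte} must be positive")
            if analyte not in self.intercepts:
                raise ValueError(f"no intercept for {analyte}")


def fit_calibration(standards: pd.DataFrame) -> HPAECCalibration:
    """Ordinary least squares per analyte from standard injections.

    ``standards`` must have columns analyte, amount, area with >= 2 levels per
    analyte.
    """
    slopes, intercepts = {}, {}
    for analyte, grp in standards.groupby("analyte"):
        if grp["amount"].nunique() < 2:
            raise ValueError(f"analyte {analyte}: need >= 2 standard levels")
        slope, intercept = np.polyfit(grp["amount"], grp["area"], 1)
        slopes[analyte] = float(slope)
        intercepts[analyte] = float(intercept)
    return HPAECCalibration(slopes=slopes, intercepts=intercepts)


def quantify_sugars(
    peak_areas: dict[str, float],
    cal: HPAECCalibration,
    resuspension_volume_ml: float,
    biomass_weight_mg: float,
) -> tuple[dict[str, float], list[str]]:
    """Back-calculate per-sugar amounts (units of the standard per mg biomass).

    amount = (area - intercept) / slope * volume / weight.  Negative
    back-calculations are floored at zero and the analyte name returned in the
    flag list.
    """
    if resuspension_volume_ml <= 0 or biomass_weight_mg <= 0:
        raise ValueError("volume and weight must be positive")
    amounts, flagged = {}, []
    for analyte, area in peak_areas.items():
        if analyte not in cal.slopes:
            raise KeyError(f"analyte {analyte!r} missing from calibration")
        conc = (area - cal.intercepts[analyte]) / cal.slopes[analyte]
        amount = conc * resuspension_volume_ml / biomass_weight_mg
        if amount < 0:
            flagged.append(analyte)
            amount = 0.0
        amounts[analyte] = amount
    return amounts, flagged


def digestion_delta(
    wood: list[BiomassSample],
    feces_normalized: list[BiomassSample],
) -> pd.DataFrame:
    """Per-fraction and per-sugar percent reduction from wood to feces.

    ``feces_normalized`` samples must already be expressed on the ingested-mass
    basis (fraction values scaled to sum to 100 - mass loss).  For each
    quantity the reduction is 100 * (mean_wood - mean_feces) / mean_wood, with
    the group SDs propagated:

        sd = 100/mean_w * sqrt(sd_f^2 + (mean_f * sd_w / mean_w)^2)

    Quantities with zero wood mean are flagged undefined (NaN reduction).
    """
    if not wood or not feces_normalized:
        raise ValueError("both sample sets must be non-empty")

    rows = []
    for kind, getter in _quantity_getters(wood + feces_normalized):
        w_vals = np.array([getter(s) for s in wood], dtype=float)
        f_vals = np.array([getter(s) for s in feces_normalized], dtype=float)
        mean_w, mean_f = w_vals.mean(), f_vals.mean()
        sd_w = w_vals.std(ddof=1) if len(w_vals) > 1 else 0.0
        sd_f = f_vals.std(ddof=1) if len(f_vals) > 1 else 0.0
        if mean_w == 0:
            reduction, sd, undefined = float("nan"), float("nan"), True
        else:
            reduction = 100.0 * (mean_w - mean_f) / mean_w
            sd = 100.0 / mean_w * math.hypot(sd_f, mean_f * sd_w / mean_w)
            undefined = False
        rows.append(
            {
                "quantity": kind,
                "wood_mean": mean_w,
                "wood_sd": sd_w,
                "feces_mean": mean_f,
                "feces_sd": sd_f,
                "reduction_pct": reduction,
                "reduction_sd": sd,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)


def _quantity_getters(samples):
    """Yield (name, getter) for each fraction and each sugar present."""
    for frac in FRACTIONS:
        yield frac, (lambda s, f=frac: s.fractions[f])
    sugar_keys = []
    for s in samples:
        for frac, sugar_map in s.sugars.items():
            for sugar in sugar_map:
                if (frac, sugar) not in sugar_keys:
                    sugar_keys.append((frac, sugar))
    for frac, sugar in sugar_keys:
        yield f"{frac}:{sugar}", (
            lambda s, f=frac, g=sugar: s.sugars.get(f, {}).get(g, 0.0)
        )
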