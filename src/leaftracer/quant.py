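"""Absolute amino-acid quantification and net :sup:`15`N allocation.

Peak areas are normalised with the dl-3-aminobutyric-acid internal standard,
inverted through per-amino-acid external calibration curves, and converted to
contents in µmol g⁻¹ DW through the extraction volume chain (0.9 ml MeOH/H₂O
fraction, 200 µl aliquot evaporated, resuspended in 50 µl by default).
Contents are combined with net labelling into net :sup:`15`N allocation —
the absolute quantity of net :sup:`15`N in each amino acid per g dry weight
per labelling period, the flux proxy of the leaf-disc assays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response (area vs concentration) of one amino acid."""

    amino_acid: str
    slope: float  # area per µM
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]  # µM, fitted range

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(
                f"{self.amino_acid}: calibration slope must be > 0, got {self.slope}"
            )

    def invert(self, area: float) -> float:
        """Concentration (µM) producing a given area; warns on extrapolation."""
        conc = (area - self.intercept) / self.slope
        lo, hi = self.conc_range
        if not (lo <= conc <= hi):
            logger.warning(
                "%s: inverted concentration %.4g µM outside fitted range "
                "[%.4g, %.4g] — extrapolating",
                self.amino_acid,
                conc,
                lo,
                hi,
            )
        return conc


@dataclass(frozen=True)
class VolumeChain:
    """Extraction volume bookkeeping from extract fraction to injected solution.

    The measured concentration refers to the final resuspension; the effective
    extract volume maps it back to the whole MeOH/H₂O fraction:
    ``effective = resuspension_ml * fraction_ml / aliquot_ml``.
    """

    fraction_ml: float = 0.9  # MeOH/H2O fraction containing the IS
    aliquot_ml: float = 0.2  # evaporated aliquot
    resuspension_ml: float = 0.05  # final resuspension volume

    @property
    def effective_volume_ml(self) -> float:
        return self.resuspension_ml * self.fraction_ml / self.aliquot_ml


#: Internal-standard concentration in the MeOH/H2O fraction (µM).
IS_EXPECTED_CONCENTRATION_UM = 111.0


@dataclass(frozen=True)
class SampleQuantRecord:
    """One (sample, amino acid) quantification measurement."""

    sample_id: str
    amino_acid: str
    peak_area: float
    internal_standard_area: float
    dry_weight_g: float
    extract_volume_ml: float | None = None  # overrides the VolumeChain if set
    internal_standard_expected_area: float | None = None

    def __post_init__(self) -> None:
        if self.peak_area < 0 or self.internal_standard_area < 0:
            raise ValueError(f"{self.sample_id}/{self.amino_acid}: negative area")
        if self.dry_weight_g <= 0:
            raise ValueError(f"{self.sample_id}: dry weight must be > 0")


def fit_calibration(
    amino_acid: str, standards: list[tuple[float, float]]
) -> CalibrationCurve:
    """Ordinary least squares line through (concentration µM, area) standards.

    Requires at least three distinct concentrations.
    """
    if len(standards) < 3:
        raise ValueError(
            f"{amino_acid}: calibration needs >= 3 points, got {len(standards)}"
        )
    conc = np.asarray([c for c, _ in standards], dtype=float)
    area = np.asarray([a for _, a in standards], dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError(f"{amino_acid}: calibration needs >= 3 distinct concentrations")
    fit = stats.linregress(conc, area)
    return CalibrationCurve(
        amino_acid=amino_acid,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def quantify(
    record: SampleQuantRecord,
    curve: CalibrationCurve,
    is_curve: CalibrationCurve | None = None,
    volumes: VolumeChain = VolumeChain(),
) -> float:
    """Amino-acid content in µmol g⁻¹ DW for one sample.

    The peak area is rescaled by the internal-standard recovery factor
    (expected IS response / observed IS area), inverted through the
    calibration curve to a concentration in the injected solution, and
    converted through the volume chain and dry weight.  The expected IS
    response is taken from ``record.internal_standard_expected_area`` if set,
    otherwise predicted from ``is_curve`` at the nominal IS concentration
    (111 µM in the fraction, scaled by the aliquot concentration factor).
    """
    if record.internal_standard_area <= 0:
        raise ValueError(
            f"{record.sample_id}/{record.amino_acid}: internal-standard area is 0"
        )
    if record.internal_standard_expected_area is not None:
        expected_is = record.internal_standard_expected_area
    elif is_curve is not None:
        # IS concentration in the injected solution after evaporation/resuspension
        conc_factor = volumes.aliquot_ml / volumes.resuspension_ml
        expected_is = (
            is_curve.slope * IS_EXPECTED_CONCENTRATION_UM * conc_factor
            + is_curve.intercept
        )
    else:
        expected_is = record.internal_standard_area  # unit recovery assumed
    corrected_area = record.peak_area * (expected_is / record.internal_standard_area)
    conc_um = curve.invert(corrected_area)  # µM in the injected solution
    volume_ml = (
        record.extract_volume_ml
        if record.extract_volume_ml is not None
        else volumes.effective_volume_ml
    )
    amount_umol = conc_um * volume_ml * 1e-3  # µmol/L * L
    content = amount_umol / record.dry_weight_g
    if content < 0:
        logger.warning(
            "%s/%s: content %.4g below 0 (area under calibration intercept); "
            "clipping to 0",
            record.sample_id,
            record.amino_acid,
            content,
        )
        content = 0.0
    return content


def net_15N_allocation(content_umol_per_g: float, mean_labelled_atoms: float) -> float:
    """Net :sup:`15`N allocation in nmol :sup:`15`N g⁻¹ DW per labelling period.

    ``allocation = content × mean_labelled_atoms × 1000`` (µmol → nmol).
    """
    return content_umol_per_g * mean_labelled_atoms * 1000.0
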