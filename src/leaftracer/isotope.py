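"""Mass-isotopologue distributions and :sup:`15`N labelling arithmetic.

An LC-MS acquisition of an AccQTag-derivatised amino acid yields one intensity
per isotopologue M+0 .. M+x\\ :sub:`max`, where *x* counts incorporated
:sup:`15`N atoms.  This module turns such raw vectors into

* *fractional labelling* — each isotopologue's share of the compound's total
  signal, the "true :sup:`15`N labelling" expressed as a fraction;
* *net labelling* — fractional labelling minus the T0 (natural-abundance)
  baseline of the same experiment, which sums to zero across isotopologues;
* *mean labelled atoms* — the signed average number of :sup:`15`N atoms gained
  per molecule, the bridge from labelling fractions to absolute net
  :sup:`15`N quantities.

Derivatisation adds an artificial M+1 signal (~20 % of each amino acid's
signal is shifted up one mass unit).  The artifact is modelled as a
one-mass-unit shift convolution with fraction ``r`` estimated from
:sup:`15`N-free external standards, and removed by exact recursive
deconvolution (:func:`correct_m1_artifact`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Theoretical natural abundance of 15N, per nitrogen atom.
NATURAL_15N_ABUNDANCE = 0.003663

_FRACTION_ATOL = 1e-9


class DegenerateInputError(ValueError):
    """Raised when an input vector carries no usable signal."""


@dataclass(frozen=True)
class AminoAcidSpec:
    """Identity and nitrogen stoichiometry of one amino acid.

    Parameters
    ----------
    name : str
        Amino-acid name, e.g. ``"proline"``.
    n_atoms : int
        Number of nitrogen atoms (proline and glutamate 1, glutamine 2).
    internal_standard : bool
        Whether this compound is the internal standard (excluded from
        biological summaries).
    """

    name: str
    n_atoms: int
    internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError(f"{self.name}: n_atoms must be >= 1, got {self.n_atoms}")


#: Nitrogen-atom counts for the amino acids tracked in the leaf-disc assays.
DEFAULT_AMINO_ACIDS: dict[str, AminoAcidSpec] = {
    spec.name: spec
    for spec in (
        AminoAcidSpec("proline", 1),
        AminoAcidSpec("glutamate", 1),
        AminoAcidSpec("glutamine", 2),
        AminoAcidSpec("aspartate", 1),
        AminoAcidSpec("asparagine", 2),
        AminoAcidSpec("alanine", 1),
        AminoAcidSpec("serine", 1),
        AminoAcidSpec("glycine", 1),
        AminoAcidSpec("gaba", 1),
        AminoAcidSpec("arginine", 4),
        AminoAcidSpec("aminobutyrate_IS", 1, internal_standard=True),
    )
}

#: Default highest isotopologue tracked by the acquisition (M+0..M+4).
DEFAULT_X_MAX = 4


@dataclass(frozen=True)
class MIDVector:
    """Intensities or fractions over isotopologues M+0..M+x_max for one compound.

    ``values[x]`` is the signal of isotopologue M+x.  A fractional vector sums
    to 1; a raw vector holds non-negative intensities in arbitrary units.
    """

    amino_acid: str
    values: tuple[float, ...]
    is_fractional: bool = False

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 1:
            raise ValueError("MIDVector needs at least one isotopologue")
        if any(v < 0 for v in vals):
            raise ValueError(
                f"{self.amino_acid}: negative isotopologue value in {vals}"
            )
        if self.is_fractional and abs(sum(vals) - 1.0) > _FRACTION_ATOL:
            raise ValueError(
                f"{self.amino_acid}: fractional MID sums to {sum(vals)!r}, not 1"
            )

    @property
    def x_max(self) -> int:
        return len(self.values) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class ArtifactModel:
    """One-mass-unit shift artifact from AccQTag derivatisation.

    ``r`` is the fraction of each isotopologue's signal observed one mass unit
    higher than its true position: ``observed(x) = (1-r) true(x) + r true(x-1)``.
    """

    r: float
    mode: str = "shift_deconvolution"  # or "subtract_standard"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r < 1.0):
            raise ValueError(f"artifact fraction r must be in [0, 1), got {self.r}")
        if self.mode not in ("shift_deconvolution", "subtract_standard"):
            raise ValueError(f"unknown artifact mode {self.mode!r}")


@dataclass(frozen=True)
class LabellingResult:
    """Fractional and net labelling for one amino acid in one sample.

    ``fractional[x]`` is isotopologue M+x's share of total signal (sums to 1);
    ``net[x]`` is that share minus the T0 baseline (sums to 0; may be negative,
    typically for M+0).  ``mean_labelled_atoms`` is ``sum_x x * net[x]``, the
    net number of :sup:`15`N atoms gained per molecule.
    """

    amino_acid: str
    fractional: tuple[float, ...]
    net: tuple[float, ...] | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        frac = tuple(float(v) for v in self.fractional)
        object.__setattr__(self, "fractional", frac)
        if abs(sum(frac) - 1.0) > _FRACTION_ATOL:
            raise ValueError(
                f"{self.amino_acid}: fractional labelling sums to {sum(frac)!r}"
            )
        if self.net is not None:
            net = tuple(float(v) for v in self.net)
            object.__setattr__(self, "net", net)
            if len(net) != len(frac):
                raise ValueError("net and fractional lengths differ")
            if abs(sum(net)) > _FRACTION_ATOL:
                raise ValueError(f"{self.amino_acid}: net labelling sums to {sum(net)!r}")

    @property
    def mean_labelled_atoms(self) -> float:
        if self.net is None:
            raise ValueError("net labelling not computed (no T0 baseline subtracted)")
        return mean_labelled_atoms(self.net)


def fractional_labelling(mid: MIDVector, sample_id: str | None = None) -> LabellingResult:
    """Normalise an isotopologue vector to fractions of total signal.

    ``fraction(x) = [M+x] / sum_y [M+y]``.

    Raises
    ------
    DegenerateInputError
        If the vector is all-zero (no signal for this amino acid).
    """
    arr = mid.as_array()
    total = arr.sum()
    if total <= 0:
        raise DegenerateInputError(
            f"all-zero isotopologue vector for {mid.amino_acid!r}"
            + (f" in sample {sample_id!r}" if sample_id else "")
        )
    frac = arr / total
    return LabellingResult(
        amino_acid=mid.amino_acid, fractional=tuple(frac), sample_id=sample_id
    )


def estimate_m1_artifact(
    standard_mids: list[MIDVector],
    baseline: float = 0.0,
    mode: str = "shift_deconvolution",
) -> ArtifactModel:
    """Estimate the derivatisation M+1 artifact from :sup:`15`N-free standards.

    ``r`` is the mean, over standards, of the M+1 fraction in excess of
    ``baseline``.  The default baseline is 0: the natural-abundance M+1 of the
    molecule itself is left in place and absorbed later by the T0 subtraction
    in :func:`net_labelling`.  Pass ``baseline = NATURAL_15N_ABUNDANCE *
    n_atoms`` to remove the theoretical natural contribution here instead.

    Raises
    ------
    ValueError
        If the standard set is empty.
    """
    if not standard_mids:
        raise ValueError("no 15N-free standards provided for artifact estimation")
    excesses = []
    for mid in standard_mids:
        frac = fractional_labelling(mid).fractional
        m1 = frac[1] if len(frac) > 1 else 0.0
        excess = m1 - baseline
        if excess < 0:
            logger.warning(
                "standard for %s has M+1 fraction %.4g below baseline %.4g; "
                "clamping excess to 0",
                mid.amino_acid,
                m1,
                baseline,
            )
            excess = 0.0
        excesses.append(excess)
    r = float(np.mean(excesses))
    return ArtifactModel(r=min(r, np.nextafter(1.0, 0.0)), mode=mode)


def _forward_shift(true: np.ndarray, r: float) -> np.ndarray:
    """Forward artifact model: shift fraction ``r`` of each peak up one unit.

    Signal shifted past the last tracked isotopologue is dropped, mirroring an
    acquisition window; callers keeping mass balance should track one spare
    isotopologue position.
    """
    obs = (1.0 - r) * true
    obs[1:] += r * true[:-1]
    return obs


def forward_m1_artifact(mid: MIDVector, artifact: ArtifactModel) -> MIDVector:
    """Apply the artifact forward model (used by simulators and as test oracle)."""
    obs = _forward_shift(mid.as_array(), artifact.r)
    if mid.is_fractional:
        obs = obs / obs.sum()
    return replace(mid, values=tuple(obs))


def correct_m1_artifact(mid: MIDVector, artifact: ArtifactModel) -> MIDVector:
    """Remove the derivatisation M+1 artifact from an observed MID.

    In ``shift_deconvolution`` mode (default) the observed vector is the
    one-unit shift convolution of the true vector,
    ``observed(x) = (1-r) true(x) + r true(x-1)``, inverted exactly by the
    recursion ``true(0) = observed(0)/(1-r)``,
    ``true(x) = (observed(x) - r*true(x-1))/(1-r)``.

    In ``subtract_standard`` mode the fraction ``r`` of total signal is simply
    moved from M+1 back to M+0 — the naive correction, kept for sensitivity
    checks.

    Negative corrected values (noise-driven) are clipped to zero with a logged
    warning; fractional vectors are then renormalised.
    """
    r = artifact.r
    obs = mid.as_array()
    if artifact.mode == "subtract_standard":
        true = obs.copy()
        if len(true) > 1:
            total = obs.sum()
            moved = min(r * total, true[1])
            true[1] -= moved
            true[0] += moved
    else:
        true = np.empty_like(obs)
        prev = 0.0
        for x in range(len(obs)):
            prev = (obs[x] - r * prev) / (1.0 - r)
            true[x] = prev
    if np.any(true < 0):
        clipped = -true[true < 0].sum()
        logger.warning(
            "artifact correction for %s clipped %.4g negative signal to 0",
            mid.amino_acid,
            clipped,
        )
        true = np.clip(true, 0.0, None)
    if mid.is_fractional:
        total = true.sum()
        if total <= 0:
            raise DegenerateInputError(
                f"artifact correction annihilated all signal for {mid.amino_acid!r}"
            )
        true = true / total
    return replace(mid, values=tuple(true))


def net_labelling(sample: LabellingResult, t0: LabellingResult) -> LabellingResult:
    """Subtract the T0 natural-abundance baseline from a sample's labelling.

    ``net(x) = fractional_sample(x) - fractional_T0(x)``; the result sums to
    zero and its M+0 component is typically negative (depletion of the
    unlabelled pool).
    """
    if sample.amino_acid != t0.amino_acid:
        raise ValueError(
            f"amino-acid mismatch: sample {sample.amino_acid!r} vs T0 {t0.amino_acid!r}"
        )
    if len(sample.fractional) != len(t0.fractional):
        raise ValueError(
            f"{sample.amino_acid}: isotopologue count mismatch "
            f"({len(sample.fractional)} vs {len(t0.fractional)})"
        )
    net = np.asarray(sample.fractional) - np.asarray(t0.fractional)
    net -= net.sum() / len(net)  # remove float residue so the sum is exactly 0
    return LabellingResult(
        amino_acid=sample.amino_acid,
        fractional=sample.fractional,
        net=tuple(net),
        sample_id=sample.sample_id,
    )


def mean_labelled_atoms(net: tuple[float, ...] | np.ndarray) -> float:
    """Net :sup:`15`N atoms gained per molecule: ``sum_x x * net(x)``."""
    arr = np.asarray(net, dtype=float)
    return float(np.dot(np.arange(len(arr)), arr))
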