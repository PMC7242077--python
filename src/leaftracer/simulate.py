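"""Synthetic raw data with the statistical structure the pipeline assumes.

The generator emulates the three raw-data streams of the leaf-disc assays:

* **Labelling** — per-molecule :sup:`15`N incorporation is independent per
  nitrogen atom, so an amino acid with ``n`` N atoms has a binomial
  isotopologue distribution: incorporation probability ``p`` (leaf-rank
  dependent) after 4 h of labelling, natural abundance ``p0 = 0.003663`` at
  T0.  The true MID is forward-convolved with the derivatisation M+1 artifact
  ``r``, scaled to intensities proportional to content, and perturbed with
  multiplicative lognormal noise.  :sup:`15`N-free standards (pure M+0 plus
  artifact) are emitted alongside.
* **qPCR** — ``Cq = intercept − log_E(expression) + N(0, sd)``; two stable
  reference genes, one deliberately unstable decoy for geNorm testing, and
  target genes whose expression follows configured per-arm/per-timepoint
  levels (defaults reproduce the strong osmotic induction, log2 FC ratio 7).
  Primer dilution series are generated from the same efficiencies.
* **Quantification** — linear calibration series and sample peak areas with
  internal-standard recovery jitter, consistent with the configured contents
  through the extraction volume chain.

Every generator takes an explicit seed and writes a ground-truth sidecar, so
the full analysis chain can be checked for parameter recovery without any
external data.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats as _sps

from leaftracer.isotope import DEFAULT_AMINO_ACIDS, DEFAULT_X_MAX, NATURAL_15N_ABUNDANCE
from leaftracer.quant import IS_EXPECTED_CONCENTRATION_UM, VolumeChain

#: Leaf ranks ordered from strong sink (young) to strong source (old) status.
DEFAULT_RANKS = ("L15", "L11", "L7", "L3")

#: Per-atom 15N incorporation probability of proline per leaf rank after 4 h
#: (the sink-to-source gradient the labelling assay resolves).
DEFAULT_PROLINE_ENRICHMENT = {"L15": 0.10, "L11": 0.07, "L7": 0.02, "L3": 0.005}


class AminoAcidSim(BaseModel):
    """Simulation parameters for one amino acid."""

    n_atoms: int = Field(ge=1)
    #: per-atom incorporation probability after labelling, by leaf rank
    enrichment: dict[str, float]
    #: content in µmol g⁻¹ DW, by leaf rank
    content: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "AminoAcidSim":
        for rank, p in self.enrichment.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"enrichment[{rank}] = {p} outside [0, 1]")
        for rank, c in self.content.items():
            if c < 0:
                raise ValueError(f"content[{rank}] = {c} must be >= 0")
        return self


class GeneSim(BaseModel):
    """Simulation parameters for one gene on the qPCR plate."""

    efficiency: float = Field(gt=1.0, le=2.2)
    #: true relative expression per (arm, timepoint); scalar = constant
    expression: dict[str, float] | float = 1.0
    #: SD of per-sample lognormal expression jitter (log2 units); reference
    #: genes are stable (small), the decoy is deliberately unstable
    stability_sd: float = Field(default=0.05, ge=0.0)
    role: str = "target"  # "reference", "target" or "decoy"


def _default_amino_acids() -> dict[str, AminoAcidSim]:
    ranks = DEFAULT_RANKS
    return {
        "proline": AminoAcidSim(
            n_atoms=1,
            enrichment=dict(DEFAULT_PROLINE_ENRICHMENT),
            content={"L15": 2.0, "L11": 1.1, "L7": 0.5, "L3": 0.5},
        ),
        "glutamate": AminoAcidSim(
            n_atoms=1,
            enrichment={r: 0.54 for r in ranks},
            content={r: 5.0 for r in ranks},
        ),
        "glutamine": AminoAcidSim(
            n_atoms=2,
            enrichment={r: 0.72 for r in ranks},
            content={r: 10.0 for r in ranks},
        ),
    }


def _default_genes() -> dict[str, GeneSim]:
    # Osmotic-shock design: arm_timepoint keys; treatment T0->T1 induction
    # of the stress-responsive P5CS1 genes gives a log2 FC ratio of 7.
    flat = {"control_T0": 1.0, "control_T1": 1.0, "treatment_T0": 1.0}
    return {
        "UBQ11": GeneSim(efficiency=1.95, expression=1.0, stability_sd=0.05, role="reference"),
        "RibS3": GeneSim(efficiency=1.98, expression=1.0, stability_sd=0.05, role="reference"),
        "DECOY": GeneSim(efficiency=1.90, expression=1.0, stability_sd=0.8, role="decoy"),
        "P5CS1c": GeneSim(
            efficiency=2.0, expression={**flat, "treatment_T1": 2.0**7}, role="target"
        ),
        "P5CS1a": GeneSim(
            efficiency=1.92, expression={**flat, "treatment_T1": 2.0**2}, role="target"
        ),
        "ProDH1a": GeneSim(
            efficiency=1.96, expression={**flat, "treatment_T1": 2.0**-2}, role="target"
        ),
    }


class SimulationConfig(BaseModel):
    """All generator parameters; defaults are the study conditions."""

    ranks: tuple[str, ...] = DEFAULT_RANKS
    amino_acids: dict[str, AminoAcidSim] = Field(default_factory=_default_amino_acids)
    artifact_r: float = Field(default=0.20, ge=0.0, lt=1.0)
    natural_abundance: float = Field(default=NATURAL_15N_ABUNDANCE, ge=0.0, le=1.0)
    noise_cv: float = Field(default=0.02, ge=0.0)  # multiplicative, intensities
    n_replicates: int = Field(default=3, ge=1)
    n_standards: int = Field(default=3, ge=1)
    x_max: int = Field(default=DEFAULT_X_MAX, ge=1)
    intensity_per_umol: float = Field(default=1e5, gt=0)
    dry_weight_g: float = Field(default=0.01, gt=0)

    # qPCR block
    genes: dict[str, GeneSim] = Field(default_factory=_default_genes)
    cq_noise_sd: float = Field(default=0.2, ge=0.0)  # cycles
    cq_intercept: float = Field(default=25.0)
    dilution_log10_steps: tuple[float, ...] = (0.0, -1.0, -2.0, -3.0)
    dilution_replicates: int = Field(default=2, ge=1)

    # quantification block
    calibration_concentrations_um: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)
    calibration_slope: float = Field(default=100.0, gt=0)  # area per µM
    is_recovery_sd: float = Field(default=0.05, ge=0.0)  # lognormal sigma

    seed: int = 0

    def rng(self, stream: str, seed: int | None = None) -> np.random.Generator:
        base = self.seed if seed is None else seed
        stream_key = zlib.crc32(stream.encode("utf-8"))  # stable across processes
        return np.random.default_rng([stream_key % (2**31), base % (2**31)])


def _binomial_mid(n_atoms: int, p: float, x_max: int) -> np.ndarray:
    """Expected MID of a compound with independent per-atom labelling."""
    mid = np.zeros(x_max + 1)
    pmf = _sps.binom.pmf(np.arange(n_atoms + 1), n_atoms, p)
    mid[: n_atoms + 1] = pmf
    return mid


def _forward_artifact(mid: np.ndarray, r: float) -> np.ndarray:
    obs = (1.0 - r) * mid
    obs[1:] += r * mid[:-1]
    return obs


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=shape)


def simulate_labelling_experiment(
    config: SimulationConfig, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Generate T0/T4h isotopologue intensity tables plus standards and truth.

    Returns a dict with keys ``intensities`` (long format: sample_id,
    timepoint, leaf_rank, replicate, amino_acid, isotopologue, intensity),
    ``standards`` (same layout) and ``truth`` (per rank × amino acid:
    configured enrichment, content, expected net M+x fractions).
    """
    rng = config.rng("labelling", seed)
    rows = []
    truth_rows = []
    for rank in config.ranks:
        for aa_name, aa in config.amino_acids.items():
            p_label = aa.enrichment[rank]
            content = aa.content[rank]
            total = content * config.intensity_per_umol
            for timepoint, p in (("T0", config.natural_abundance), ("T4h", p_label)):
                true_mid = _binomial_mid(aa.n_atoms, p, config.x_max)
                observed = _forward_artifact(true_mid, config.artifact_r) * total
                for rep in range(1, config.n_replicates + 1):
                    noisy = observed * _lognormal_noise(
                        rng, config.noise_cv, observed.shape
                    )
                    sample_id = f"{rank}_{timepoint}_r{rep}"
                    for x, val in enumerate(noisy):
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "timepoint": timepoint,
                                "leaf_rank": rank,
                                "replicate": rep,
                                "amino_acid": aa_name,
                                "isotopologue": x,
                                "intensity": val,
                            }
                        )
            net_expected = _binomial_mid(aa.n_atoms, p_label, config.x_max) - _binomial_mid(
                aa.n_atoms, config.natural_abundance, config.x_max
            )
            truth_rows.append(
                {
                    "leaf_rank": rank,
                    "amino_acid": aa_name,
                    "enrichment": p_label,
                    "content_umol_per_g": content,
                    "net_mean_labelled_atoms": float(
                        np.dot(np.arange(config.x_max + 1), net_expected)
                    ),
                }
            )

    std_rows = []
    pure = np.zeros(config.x_max + 1)
    pure[0] = 1.0
    std_observed = _forward_artifact(pure, config.artifact_r)
    for aa_name in config.amino_acids:
        for rep in range(1, config.n_standards + 1):
            noisy = (
                std_observed
                * config.intensity_per_umol
                * _lognormal_noise(rng, config.noise_cv, std_observed.shape)
            )
            for x, val in enumerate(noisy):
                std_rows.append(
                    {
                        "sample_id": f"std_{aa_name}_r{rep}",
                        "timepoint": "standard",
                        "leaf_rank": "",
                        "replicate": rep,
                        "amino_acid": aa_name,
                        "isotopologue": x,
                        "intensity": val,
                    }
                )

    return {
        "intensities": pd.DataFrame(rows),
        "standards": pd.DataFrame(std_rows),
        "truth": pd.DataFrame(truth_rows),
    }


def simulate_qpcr_plate(
    config: SimulationConfig, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Generate a Cq plate, per-primer dilution series and ground truth.

    Plate layout: ``n_replicates`` biological samples per (arm, timepoint)
    condition appearing in any gene's expression map, every gene measured in
    duplicate technical replicates.
    """
    rng = config.rng("qpcr", seed)
    conditions: list[tuple[str, str]] = []
    for gene in config.genes.values():
        if isinstance(gene.expression, dict):
            for key in gene.expression:
                arm, timepoint = key.rsplit("_", 1)
                if (arm, timepoint) not in conditions:
                    conditions.append((arm, timepoint))
    if not conditions:
        conditions = [("control", "T0")]

    cq_rows = []
    meta_rows = []
    truth_rows = []
    for arm, timepoint in conditions:
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{arm}_{timepoint}_r{rep}"
            meta_rows.append(
                {"sample_id": sample_id, "arm": arm, "timepoint": timepoint, "replicate": rep}
            )
            for gene_name, gene in config.genes.items():
                if isinstance(gene.expression, dict):
                    expr = gene.expression.get(f"{arm}_{timepoint}")
                    if expr is None:
                        continue
                else:
                    expr = gene.expression
                # per-sample biological jitter (log2 space)
                expr_sample = expr * 2.0 ** rng.normal(0.0, gene.stability_sd)
                cq_true = config.cq_intercept - math.log(expr_sample, gene.efficiency)
                for tech in (1, 2):
                    cq_rows.append(
                        {
                            "sample_id": sample_id,
                            "gene": gene_name,
                            "replicate": tech,
                            "Cq": cq_true + rng.normal(0.0, config.cq_noise_sd),
                        }
                    )
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "gene": gene_name,
                        "arm": arm,
                        "timepoint": timepoint,
                        "true_expression": expr,
                        "sampled_expression": expr_sample,
                    }
                )

    dilution_rows = []
    for gene_name, gene in config.genes.items():
        for log10_input in config.dilution_log10_steps:
            # Cq = intercept - log_E(10^log10_input)
            cq_true = config.cq_intercept - log10_input * math.log(10.0) / math.log(
                gene.efficiency
            )
            for rep in range(1, config.dilution_replicates + 1):
                dilution_rows.append(
                    {
                        "gene": gene_name,
                        "log10_input": log10_input,
                        "replicate": rep,
                        "Cq": cq_true + rng.normal(0.0, config.cq_noise_sd),
                    }
                )

    gene_rows = [
        {
            "gene": name,
            "role": gene.role,
            "true_efficiency": gene.efficiency,
            "stability_sd": gene.stability_sd,
        }
        for name, gene in config.genes.items()
    ]

    return {
        "cq": pd.DataFrame(cq_rows),
        "dilution_series": pd.DataFrame(dilution_rows),
        "metadata": pd.DataFrame(meta_rows),
        "genes": pd.DataFrame(gene_rows),
        "truth": pd.DataFrame(truth_rows),
    }


def simulate_quant_tables(
    config: SimulationConfig, seed: int | None = None, volumes: VolumeChain = VolumeChain()
) -> dict[str, pd.DataFrame]:
    """Generate calibration series and sample peak-area tables with truth.

    Sample areas are consistent with the configured contents pushed through
    the extraction volume chain; the internal standard carries lognormal
    recovery jitter shared by all compounds of a sample.
    """
    rng = config.rng("quant", seed)
    cal_rows = []
    for aa_name in list(config.amino_acids) + ["aminobutyrate_IS"]:
        for conc in config.calibration_concentrations_um:
            area = config.calibration_slope * conc
            area *= float(_lognormal_noise(rng, config.noise_cv, ()))
            cal_rows.append({"amino_acid": aa_name, "concentration_um": conc, "area": area})

    is_conc_injected = IS_EXPECTED_CONCENTRATION_UM * volumes.aliquot_ml / volumes.resuspension_ml
    is_expected_area = config.calibration_slope * is_conc_injected

    sample_rows = []
    truth_rows = []
    for rank in config.ranks:
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{rank}_r{rep}"
            recovery = float(np.exp(rng.normal(0.0, config.is_recovery_sd)))
            is_area = is_expected_area * recovery * float(
                _lognormal_noise(rng, config.noise_cv, ())
            )
            for aa_name, aa in config.amino_acids.items():
                content = aa.content[rank]
                amount_umol = content * config.dry_weight_g
                conc_um = amount_umol / (volumes.effective_volume_ml * 1e-3)
                area = config.calibration_slope * conc_um * recovery
                area *= float(_lognormal_noise(rng, config.noise_cv, ()))
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "amino_acid": aa_name,
                        "area": area,
                        "is_area": is_area,
                        "dry_weight_g": config.dry_weight_g,
                    }
                )
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "leaf_rank": rank,
                        "amino_acid": aa_name,
                        "content_umol_per_g": content,
                    }
                )

    return {
        "calibration": pd.DataFrame(cal_rows),
        "samples": pd.DataFrame(sample_rows),
        "truth": pd.DataFrame(truth_rows),
    }
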