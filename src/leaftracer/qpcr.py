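"""Efficiency-corrected relative qPCR expression, geNorm stability, fold changes.

Relative expression of a target gene is the efficiency-corrected quantity
``E_t^(-Cq_t)`` normalised to the geometric mean of the same quantity for the
reference genes (the leaf-disc assays use *BnaC.UBQ11* and *BnaC.RibS3*):

    RE = E_t^(-Cq_t) / geomean_j( E_j^(-Cq_j) )

Primer efficiencies come from dilution-series slopes, ``E = 10^(-1/slope)``.
Candidate reference genes are ranked with the geNorm stability measure
``M_j`` — the mean, over the other candidates, of the standard deviation
across samples of the pairwise log2 expression ratio — with the classical
iterative exclusion of the least stable gene.  Fold changes between
consecutive time points and log2 fold-change ratios between treatment and
control arms summarise the time courses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimerSpec:
    """Amplification factor per cycle for one primer pair (1 < E <= 2.2)."""

    gene: str
    efficiency: float
    slope: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.2):
            raise ValueError(
                f"{self.gene}: efficiency must be in (1, 2.2], got {self.efficiency}"
            )


def primer_efficiency(
    gene: str, dilution_series: list[tuple[float, float]]
) -> PrimerSpec:
    """Primer efficiency from a serial dilution: (log10 relative input, Cq) points.

    Needs at least three points spanning at least two log10 units; the OLS
    slope of Cq vs log10 input must be negative (more template, earlier Cq),
    and ``E = 10^(-1/slope)``.
    """
    if len(dilution_series) < 3:
        raise ValueError(f"{gene}: dilution series needs >= 3 points")
    log_input = np.asarray([x for x, _ in dilution_series], dtype=float)
    cq = np.asarray([c for _, c in dilution_series], dtype=float)
    if log_input.max() - log_input.min() < 2.0:
        raise ValueError(
            f"{gene}: dilution series must span >= 2 log10 units "
            f"(spans {log_input.max() - log_input.min():.2f})"
        )
    fit = stats.linregress(log_input, cq)
    if fit.slope >= 0:
        raise ValueError(
            f"{gene}: dilution-series slope {fit.slope:.3f} is not negative "
            "(inverted series?)"
        )
    e = 10.0 ** (-1.0 / fit.slope)
    return PrimerSpec(
        gene=gene, efficiency=e, slope=float(fit.slope), r_squared=float(fit.rvalue**2)
    )


def relative_expression(
    target_cq: float,
    target_primer: PrimerSpec,
    refs: list[tuple[float, PrimerSpec]],
) -> float:
    """Efficiency-corrected expression normalised to reference genes.

    ``RE = E_t^(-Cq_t) / geomean_j(E_j^(-Cq_j))`` over the reference genes j.
    Computed in log space for numerical stability.
    """
    if not refs:
        raise ValueError("at least one reference gene is required")
    if not math.isfinite(target_cq):
        raise ValueError(f"{target_primer.gene}: non-finite Cq")
    log_target = -target_cq * math.log(target_primer.efficiency)
    log_refs = []
    for cq, primer in refs:
        if not math.isfinite(cq):
            raise ValueError(f"reference {primer.gene}: non-finite Cq")
        log_refs.append(-cq * math.log(primer.efficiency))
    return math.exp(log_target - float(np.mean(log_refs)))


def genorm_stability(expression: pd.DataFrame) -> pd.DataFrame:
    """geNorm M value for each candidate reference gene, ranked by stability.

    ``expression`` is a samples × genes table of positive relative quantities.
    For gene j, ``M_j`` is the mean over the other genes k of the standard
    deviation (ddof=1) across samples of ``log2(a_j / a_k)``; lower M means
    more stable.  The returned frame has one row per gene with columns
    ``gene, M, rank, exclusion_order`` — ``exclusion_order`` is the step at
    which geNorm's iterative procedure would discard the gene (1 = first
    discarded, i.e. least stable; the final two genes share the last step).
    """
    if expression.shape[1] < 3:
        raise ValueError(
            f"geNorm needs >= 3 candidate genes, got {expression.shape[1]}"
        )
    if expression.shape[0] < 2:
        raise ValueError("geNorm needs >= 2 samples")
    values = expression.to_numpy(dtype=float)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("geNorm requires strictly positive, finite expression values")
    genes = list(expression.columns)
    log2 = np.log2(values)

    def m_values(cols: list[int]) -> dict[int, float]:
        sds = {
            (j, k): float(np.std(log2[:, j] - log2[:, k], ddof=1))
            for j, k in combinations(cols, 2)
        }
        out = {}
        for j in cols:
            others = [sds[tuple(sorted((j, k)))] for k in cols if k != j]
            out[j] = float(np.mean(others))
        return out

    all_cols = list(range(len(genes)))
    full_m = m_values(all_cols)

    # iterative exclusion of the least stable gene
    remaining = list(all_cols)
    exclusion: dict[int, int] = {}
    step = 1
    while len(remaining) > 2:
        current = m_values(remaining)
        worst = max(remaining, key=lambda j: (current[j], genes[j]))
        exclusion[worst] = step
        remaining.remove(worst)
        step += 1
    for j in remaining:
        exclusion[j] = step

    out = pd.DataFrame(
        {
            "gene": genes,
            "M": [full_m[j] for j in all_cols],
            "exclusion_order": [exclusion[j] for j in all_cols],
        }
    )
    out = out.sort_values(["M", "gene"]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def fold_change_ratio(
    re_treat_t1: float, re_treat_t0: float, re_ctrl_t1: float, re_ctrl_t0: float
) -> tuple[float, float, float]:
    """Fold changes between consecutive time points and their log2 ratio.

    ``FC = RE_t1 / RE_t0`` within each arm;
    ``log2_fc_ratio = log2(FC_treatment / FC_control)``.
    """
    for name, v in (
        ("re_treat_t1", re_treat_t1),
        ("re_treat_t0", re_treat_t0),
        ("re_ctrl_t1", re_ctrl_t1),
        ("re_ctrl_t0", re_ctrl_t0),
    ):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be a positive finite number, got {v}")
    fc_treat = re_treat_t1 / re_treat_t0
    fc_ctrl = re_ctrl_t1 / re_ctrl_t0
    return fc_treat, fc_ctrl, math.log2(fc_treat / fc_ctrl)


class QPCRExperiment:
    """A qPCR plate analysis (Model half of the Model/Results pair).

    Parameters
    ----------
    cq : pandas.DataFrame
        Long-format plate with columns ``sample_id, gene, replicate, Cq``.
        Technical replicates are averaged per (sample, gene) before use;
        undetected wells are encoded as missing rows or NaN Cq, never Cq=40.
    primers : mapping gene -> PrimerSpec
        Measured efficiencies for every gene on the plate.
    reference_genes : list of str
        Genes used for normalisation (default the two stable reference genes
        of the leaf-disc assays).
    metadata : pandas.DataFrame, optional
        Per-sample annotation (``sample_id`` plus e.g. ``arm, timepoint``),
        merged into the results table and used by
        :meth:`ExpressionResults.fold_change_table`.
    """

    DEFAULT_REFERENCES = ("UBQ11", "RibS3")

    def __init__(
        self,
        cq: pd.DataFrame,
        primers: dict[str, PrimerSpec],
        reference_genes: list[str] | None = None,
        metadata: pd.DataFrame | None = None,
    ) -> None:
        for col in ("sample_id", "gene", "Cq"):
            if col not in cq.columns:
                raise ValueError(f"Cq table lacks column {col!r}")
        self.cq = cq.copy()
        self.primers = dict(primers)
        self.reference_genes = list(
            reference_genes
            if reference_genes is not None
            else [g for g in self.DEFAULT_REFERENCES if g in self.primers]
        )
        if not self.reference_genes:
            raise ValueError("no reference genes specified or recognised")
        for g in self.reference_genes:
            if g not in self.primers:
                raise ValueError(f"no primer efficiency for reference gene {g!r}")
        self.metadata = None if metadata is None else metadata.copy()

    @classmethod
    def from_csv(cls, cq_path, primers: dict[str, PrimerSpec], **kwargs):
        return cls(pd.read_csv(cq_path), primers, **kwargs)

    def _mean_cq(self) -> pd.DataFrame:
        """Average technical replicates; NaN Cq wells are dropped first."""
        cq = self.cq.dropna(subset=["Cq"])
        return cq.groupby(["sample_id", "gene"], as_index=False)["Cq"].mean()

    def fit(self) -> "ExpressionResults":
        """Compute per-sample relative expression for every non-reference gene."""
        mean_cq = self._mean_cq()
        wide = mean_cq.pivot(index="sample_id", columns="gene", values="Cq")
        rows = []
        for sample, row in wide.iterrows():
            refs = []
            missing_ref = False
            for g in self.reference_genes:
                if g not in row or not math.isfinite(row[g]):
                    logger.warning(
                        "sample %s: reference gene %s has no Cq; sample excluded",
                        sample,
                        g,
                    )
                    missing_ref = True
                    break
                refs.append((float(row[g]), self.primers[g]))
            if missing_ref:
                continue
            for gene in wide.columns:
                if gene in self.reference_genes:
                    continue
                cq_val = row.get(gene, float("nan"))
                if not math.isfinite(cq_val):
                    rows.append(
                        {"sample_id": sample, "gene": gene, "relative_expression": np.nan}
                    )
                    continue
                primer = self.primers.get(gene)
                if primer is None:
                    raise ValueError(f"no primer efficiency for gene {gene!r}")
                re_val = relative_expression(float(cq_val), primer, refs)
                rows.append(
                    {"sample_id": sample, "gene": gene, "relative_expression": re_val}
                )
        table = pd.DataFrame(rows)
        if self.metadata is not None and not table.empty:
            table = table.merge(self.metadata, on="sample_id", how="left")
        return ExpressionResults(model=self, table=table)


@dataclass
class ExpressionResults:
    """Per-sample relative expression plus fold-change summaries."""

    model: QPCRExperiment
    table: pd.DataFrame  # sample_id, gene, relative_expression [+ metadata]

    def mean_expression(self, by: list[str]) -> pd.DataFrame:
        """Geometric-mean relative expression grouped by ``["gene"] + by``."""
        t = self.table.dropna(subset=["relative_expression"])
        return (
            t.groupby(["gene"] + by, as_index=False)["relative_expression"]
            .agg(lambda v: float(np.exp(np.mean(np.log(v)))))
        )

    def fold_change_table(
        self,
        t0: str,
        t1: str,
        treatment_arm: str = "treatment",
        control_arm: str = "control",
        arm_col: str = "arm",
        time_col: str = "timepoint",
    ) -> pd.DataFrame:
        """Per-gene FC_treatment, FC_control and log2(FC ratio) between two times.

        Mean relative expression (geometric) is computed per (gene, arm,
        timepoint); genes missing any of the four cells are reported with NaN
        (not detected) rather than dropped.
        """
        means = self.mean_expression([arm_col, time_col])
        rows = []
        for gene, grp in means.groupby("gene"):
            cell = {
                (r[arm_col], r[time_col]): r["relative_expression"]
                for _, r in grp.iterrows()
            }
            try:
                fc_t, fc_c, log2_ratio = fold_change_ratio(
                    cell[(treatment_arm, t1)],
                    cell[(treatment_arm, t0)],
                    cell[(control_arm, t1)],
                    cell[(control_arm, t0)],
                )
            except KeyError:
                fc_t = fc_c = log2_ratio = np.nan
            rows.append(
                {
                    "gene": gene,
                    "fc_treatment": fc_t,
                    "fc_control": fc_c,
                    "log2_fc_ratio": log2_ratio,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        t = self.table.dropna(subset=["relative_expression"])
        lines = [
            "qPCR relative expression",
            "=" * 24,
            f"reference genes: {', '.join(self.model.reference_genes)}",
            f"samples: {t['sample_id'].nunique()}  target genes: {t['gene'].nunique()}",
        ]
        agg = t.groupby("gene")["relative_expression"].agg(["median", "min", "max"])
        for gene, row in agg.iterrows():
            lines.append(
                f"  {gene:<16s} RE median {row['median']:.3g} "
                f"(range {row['min']:.3g} – {row['max']:.3g})"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
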