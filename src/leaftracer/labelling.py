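"""Whole-experiment :sup:`15`N labelling analysis (Model/Results interface).

:class:`LabellingExperiment` is built from a long-format intensity table —
one row per ``(sample_id, timepoint, amino_acid, isotopologue, intensity)`` —
plus the :sup:`15`N-free standards used for artifact estimation.  ``fit()``
runs the full chain (artifact estimation → correction → fractional labelling
→ T0 subtraction → mean labelled atoms) and returns a
:class:`LabellingResults` carrying tidy result tables and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from leaftracer.isotope import (
    DEFAULT_AMINO_ACIDS,
    AminoAcidSpec,
    ArtifactModel,
    MIDVector,
    correct_m1_artifact,
    estimate_m1_artifact,
    fractional_labelling,
    net_labelling,
)

REQUIRED_COLUMNS = ("sample_id", "timepoint", "amino_acid", "isotopologue", "intensity")

#: Timepoint label identifying the natural-abundance baseline samples.
T0_LABEL = "T0"


def _mids_from_long(df: pd.DataFrame) -> dict[tuple[str, str], MIDVector]:
    """Pivot long rows into one MIDVector per (sample_id, amino_acid)."""
    mids: dict[tuple[str, str], MIDVector] = {}
    for (sample, aa), grp in df.groupby(["sample_id", "amino_acid"], sort=True):
        grp = grp.sort_values("isotopologue")
        x = grp["isotopologue"].to_numpy()
        if not np.array_equal(x, np.arange(len(x))):
            raise ValueError(
                f"sample {sample!r}, {aa!r}: isotopologues must be 0..x_max "
                f"without gaps, got {list(x)}"
            )
        mids[(str(sample), str(aa))] = MIDVector(
            amino_acid=str(aa), values=tuple(grp["intensity"].to_numpy())
        )
    return mids


class LabellingExperiment:
    """One :sup:`15`N labelling experiment (T0 + labelled samples + standards).

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format intensities with columns ``sample_id, timepoint,
        amino_acid, isotopologue, intensity``.
    standards : pandas.DataFrame, optional
        Same layout (``timepoint`` ignored) for the :sup:`15`N-free external
        standards.  If omitted, no artifact correction is applied (r = 0).
    amino_acids : mapping of name -> AminoAcidSpec, optional
        Nitrogen stoichiometry; defaults cover the amino acids of the
        leaf-disc assays.
    artifact_mode : {"shift_deconvolution", "subtract_standard"}
        How the M+1 derivatisation artifact is removed.
    artifact_baseline : float
        Baseline M+1 fraction attributed to the standard molecule itself
        (default 0; the T0 subtraction absorbs natural abundance).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        standards: pd.DataFrame | None = None,
        amino_acids: dict[str, AminoAcidSpec] | None = None,
        artifact_mode: str = "shift_deconvolution",
        artifact_baseline: float = 0.0,
    ) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"intensity table lacks columns {missing}")
        self.data = data.copy()
        self.standards = None if standards is None else standards.copy()
        self.amino_acids = dict(amino_acids or DEFAULT_AMINO_ACIDS)
        self.artifact_mode = artifact_mode
        self.artifact_baseline = artifact_baseline

    @classmethod
    def from_csv(
        cls, data_path, standards_path=None, **kwargs
    ) -> "LabellingExperiment":
        data = pd.read_csv(data_path)
        standards = None if standards_path is None else pd.read_csv(standards_path)
        return cls(data, standards=standards, **kwargs)

    def _estimate_artifacts(self) -> dict[str, ArtifactModel]:
        """Per-amino-acid artifact fraction from this batch's standards."""
        artifacts: dict[str, ArtifactModel] = {}
        if self.standards is None:
            return artifacts
        std_mids = _mids_from_long(self.standards)
        by_aa: dict[str, list[MIDVector]] = {}
        for (_, aa), mid in std_mids.items():
            by_aa.setdefault(aa, []).append(mid)
        for aa, mids in by_aa.items():
            artifacts[aa] = estimate_m1_artifact(
                mids, baseline=self.artifact_baseline, mode=self.artifact_mode
            )
        return artifacts

    def fit(self) -> "LabellingResults":
        """Run the correction → fractional → net labelling chain."""
        artifacts = self._estimate_artifacts()
        mids = _mids_from_long(self.data)
        timepoint = {
            str(s): str(t)
            for s, t in self.data[["sample_id", "timepoint"]]
            .drop_duplicates()
            .itertuples(index=False)
        }

        fractional: dict[tuple[str, str], "pd.Series"] = {}
        results = {}
        for (sample, aa), mid in mids.items():
            artifact = artifacts.get(aa)
            if artifact is not None:
                mid = correct_m1_artifact(mid, artifact)
            # isotopologues beyond the compound's N count cannot carry 15N;
            # after artifact removal they are pure noise, so drop them before
            # normalising (the acquisition window M+0..M+4 is wider than any
            # tracked amino acid's nitrogen stoichiometry)
            spec = self.amino_acids.get(aa)
            if spec is not None and mid.x_max > spec.n_atoms:
                mid = MIDVector(aa, mid.values[: spec.n_atoms + 1])
            results[(sample, aa)] = fractional_labelling(mid, sample_id=sample)

        # T0 baseline: mean fractional labelling over T0 replicates, per amino acid
        t0_frac: dict[str, np.ndarray] = {}
        for (sample, aa), res in results.items():
            if timepoint[sample] == T0_LABEL:
                t0_frac.setdefault(aa, []).append(np.asarray(res.fractional))
        t0_mean = {aa: np.mean(vs, axis=0) for aa, vs in t0_frac.items()}

        rows = []
        for (sample, aa), res in sorted(results.items()):
            if aa in t0_mean:
                from leaftracer.isotope import LabellingResult

                baseline = LabellingResult(amino_acid=aa, fractional=tuple(t0_mean[aa]))
                res = net_labelling(res, baseline)
            for x, f in enumerate(res.fractional):
                rows.append(
                    {
                        "sample_id": sample,
                        "timepoint": timepoint[sample],
                        "amino_acid": aa,
                        "isotopologue": x,
                        "fractional": f,
                        "net": res.net[x] if res.net is not None else np.nan,
                    }
                )
        table = pd.DataFrame(rows)
        return LabellingResults(model=self, table=table, artifacts=artifacts)


@dataclass
class LabellingResults:
    """Fitted labelling chain: tidy per-isotopologue table plus summaries."""

    model: LabellingExperiment
    table: pd.DataFrame  # sample_id, timepoint, amino_acid, isotopologue, fractional, net
    artifacts: dict[str, ArtifactModel] = field(default_factory=dict)

    def mean_labelled_atoms(self) -> pd.DataFrame:
        """Net :sup:`15`N atoms per molecule, one row per (sample, amino acid)."""
        t = self.table.dropna(subset=["net"])
        out = (
            t.assign(weighted=t["isotopologue"] * t["net"])
            .groupby(["sample_id", "timepoint", "amino_acid"], as_index=False)["weighted"]
            .sum()
            .rename(columns={"weighted": "mean_labelled_atoms"})
        )
        return out

    def summary(self) -> str:
        """Human-readable per-amino-acid summary of the fitted experiment."""
        lines = ["15N labelling experiment", "=" * 24]
        if self.artifacts:
            lines.append("M+1 artifact fractions (from 15N-free standards):")
            for aa, art in sorted(self.artifacts.items()):
                lines.append(f"  {aa:<12s} r = {art.r:.4f}  [{art.mode}]")
        mla = self.mean_labelled_atoms()
        labelled = mla[mla["timepoint"] != T0_LABEL]
        if not labelled.empty:
            lines.append("Mean net 15N atoms per molecule (labelled samples):")
            agg = labelled.groupby("amino_acid")["mean_labelled_atoms"].agg(
                ["mean", "std", "count"]
            )
            for aa, row in agg.iterrows():
                sd = 0.0 if np.isnan(row["std"]) else row["std"]
                lines.append(
                    f"  {aa:<12s} {row['mean']:+.4f} ± {sd:.4f} (n={int(row['count'])})"
                )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
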