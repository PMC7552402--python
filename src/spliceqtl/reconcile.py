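"""Direction-of-effect reconciliation across measurement modes.

The same SNP can show opposite effect signs on junction-restricted
(probe-style) and total (RNA-seq-style) expression of one gene when its
effects on coding and intron-retaining splice variants have opposite signs.
This module fits the QTL model per measurement mode -- probe log2 intensity,
log2 total FPKM, and each normalized junction -- and classifies the result
as concordant or flipped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    probe_junction_of,
    render_measurements,
    sample_junction_counts,
    simulate_variant_abundances,
)
from .expression import adjustment_design
from .junctions import JunctionCountMatrix, normalize_junction_counts
from .models import EffectSpec, GeneModel, GenotypeMatrix, MeasurementSet, QtlResult
from .qtl import fit_qtl


def simulate_measurement_set(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    gene: GeneModel,
    spec: EffectSpec,
    seed: int = 0,
    *,
    read_length: int = 75,
    depth_factor: float = 100.0,
    probe_noise_sd: float = 0.1,
) -> MeasurementSet:
    """All three measurement modes for one simulated gene.

    Simulates variant abundances, draws count-level split-read and library
    totals, normalizes the junction counts, and renders the probe-style and
    total-FPKM signals. One seed drives every stage.
    """
    s = [int(x) for x in np.random.SeedSequence(seed).generate_state(3)]
    abundances = simulate_variant_abundances(genotypes, covariates, gene, spec, seed=s[0])
    counts, gene_reads, library = sample_junction_counts(
        abundances, gene, read_length, depth_factor, seed=s[1]
    )
    jcm = JunctionCountMatrix(
        junctions=gene.junctions,
        samples=list(counts.index),
        raw_counts=counts,
        library_sizes=library,
        gene_read_counts=gene_reads.to_frame(gene.gene_id),
    )
    norm = normalize_junction_counts(jcm)
    ms = render_measurements(
        abundances, gene, probe_junction_of(gene), probe_noise_sd, seed=s[2],
        depth_factor=depth_factor,
    )
    ms.junction_counts = counts
    ms.library_sizes = library
    ms.gene_read_counts = gene_reads
    ms.normalized_junctions = norm.values
    return ms


@dataclass
class ModeResult:
    mode: str
    beta: float
    se: float
    p_value: float
    genotype_high_expression: Optional[str]
    testable: bool


@dataclass
class DirectionReport:
    """Per-mode QTL directions for one SNP plus the flip classification.

    ``flip_flag`` is True when probe- and total-mode betas are both
    significant (p < alpha) with opposite signs, False when both are
    testable without that pattern, and None when either mode is untestable.
    """

    snp_id: str
    alpha: float
    modes: dict[str, ModeResult] = field(default_factory=dict)
    flip_flag: Optional[bool] = None

    @property
    def junction_modes(self) -> list[str]:
        return [m for m in self.modes if m.startswith("junction:")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": self.snp_id,
                    "mode": m.mode,
                    "beta": m.beta,
                    "se": m.se,
                    "p_value": m.p_value,
                    "genotype_high_expression": m.genotype_high_expression,
                    "testable": m.testable,
                    "flip_flag": self.flip_flag,
                }
                for m in self.modes.values()
            ]
        )

    def digest(self) -> str:
        lines = [f"Direction profile for {self.snp_id} (significance gate p < {self.alpha}):"]
        for m in self.modes.values():
            sig = "significant" if (m.testable and m.p_value < self.alpha) else "not significant"
            direction = "up" if m.beta > 0 else "down"
            lines.append(
                f"  {m.mode:<28s} beta={m.beta:+.4g} p={m.p_value:.3g} "
                f"({sig}; alt allele {direction}; high genotype {m.genotype_high_expression})"
            )
        if self.flip_flag is None:
            lines.append("  flip: undefined (a mode was untestable)")
        elif self.flip_flag:
            lines.append(
                "  flip: YES -- junction-restricted and total expression disagree in sign,"
            )
            lines.append(
                "        the signature of opposite genotype effects on coding vs intron-retaining variants"
            )
        else:
            lines.append("  flip: no -- measurement modes agree in direction")
        return "\n".join(lines)


def direction_profile(
    snp_id: str,
    measurements: MeasurementSet,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    *,
    alpha: float = 0.05,
    maf_threshold: float = 0.05,
    smoking_mode: str = "current",
) -> DirectionReport:
    """Fit the dosage model per measurement mode and classify the directions.

    Modes: ``probe`` (log2 junction-restricted intensity, as-is), ``total``
    (log2 of total FPKM), and ``junction:<label>`` for every normalized
    junction in the measurement set. All modes share the age/sex/smoking
    covariates of the QTL engine.
    """
    info = genotypes.snp_info(snp_id)
    dosage = genotypes.dosage_of(snp_id)
    freq = np.nanmean(dosage) / 2.0
    if min(freq, 1 - freq) < maf_threshold:
        raise ValueError(
            f"{snp_id} fails the MAF filter ({min(freq, 1 - freq):.3f} < {maf_threshold})"
        )
    samples = list(measurements.probe_log2.index)
    order = {s: i for i, s in enumerate(genotypes.samples)}
    idx = [order[s] for s in samples]
    dosage = dosage[idx]
    cov = covariates.set_index("sample_id").loc[samples].reset_index()
    design = adjustment_design(cov, smoking_mode=smoking_mode)
    design = design.loc[samples, ["age", "sex_male", "smoking_current"]].to_numpy()

    series = {
        "probe": measurements.probe_log2.loc[samples].to_numpy(dtype=float),
        "total": np.log2(measurements.total_fpkm.loc[samples].to_numpy(dtype=float)),
    }
    if measurements.normalized_junctions is not None:
        for col in measurements.normalized_junctions.columns:
            series[f"junction:{col}"] = (
                measurements.normalized_junctions.loc[samples, col].to_numpy(dtype=float)
            )

    report = DirectionReport(snp_id=snp_id, alpha=alpha)
    for mode, values in series.items():
        r: QtlResult = fit_qtl(
            values, dosage, design,
            snp_id=snp_id, feature_id=mode,
            ref=info["ref"], alt=info["alt"],
        )
        report.modes[mode] = ModeResult(
            mode=mode, beta=r.beta, se=r.se, p_value=r.p_value,
            genotype_high_expression=r.genotype_high_expression, testable=r.testable,
        )
    probe, total = report.modes["probe"], report.modes["total"]
    if probe.testable and total.testable:
        both_sig = probe.p_value < alpha and total.p_value < alpha
        report.flip_flag = bool(both_sig and probe.beta * total.beta < 0)
    return report
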