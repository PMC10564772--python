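"""Truth-based evaluation of a pipeline run on a synthetic study.

Used by the test suite and the acceptance script to measure how well the
masking procedure separates planted light-responsive genes from planted
development genes, and to build the worked-example summaries from published
count tables.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from dataclasses import dataclass, field

import pandas as pd

from . import synthetic_data as sd
from .contrast_masking import MaskingRow, development_set, mask_development
from .diffexpr import DOWN, UP, DirectionalGeneSet, add_qvalues, call_de, de_test
from .expression_qc import ExpressionMatrix
from .synthetic_data import SyntheticTruth


@dataclass
class MaskingAnalysis:
    """All DE/masking artifacts of one synthetic default study."""

    design: pd.DataFrame
    matrix: ExpressionMatrix
    truth: SyntheticTruth
    within: dict[str, DirectionalGeneSet]
    between: dict[str, DirectionalGeneSet]
    dev_set: set[str]
    retained: dict[str, DirectionalGeneSet]
    rows: list[MaskingRow] = field(default_factory=list)


def sample_group(design: pd.DataFrame, genotype: str, condition: str) -> list[str]:
    rows = design[(design["genotype"] == genotype) & (design["condition"] == condition)]
    return list(rows["sample_id"])


def run_masking_analysis(
    seed: int, params: sd.SimulationParams | None = None, q_cutoff: float = 0.01
) -> MaskingAnalysis:
    """Simulate a default study and run the within/between DE + masking chain."""
    params = params or sd.SimulationParams(seed=seed)
    design = sd.generate_design(3, seed=seed, dev_stage=params.dev_stage)
    matrix, truth = sd.generate_counts(design, params)
    within = {}
    for geno in sd.GENOTYPES:
        res = add_qvalues(
            de_test(matrix, sample_group(design, geno, "M"), sample_group(design, geno, "F"))
        )
        within[geno] = call_de(res, q_cutoff, label=geno)
    between = {}
    for other in ("G_intermediate", "G_sensitive"):
        res = add_qvalues(
            de_test(
                matrix,
                sample_group(design, "G_insensitive", "M"),
                sample_group(design, other, "M"),
            )
        )
        between[other] = call_de(res, q_cutoff, label=f"vs_{other}", condition="M")
    dev = development_set(between["G_intermediate"], between["G_sensitive"])
    retained, rows = {}, []
    for geno in sd.GENOTYPES:
        r, row = mask_development(within[geno], dev)
        row.genotype = geno
        retained[geno] = r
        rows.append(row)
    return MaskingAnalysis(design, matrix, truth, within, between, dev, retained, rows)


def light_precision_recall(
    truth: SyntheticTruth, retained_sets: Iterable[DirectionalGeneSet]
) -> tuple[float, float]:
    """Precision/recall of the union of retained ("light") sets vs planted truth."""
    retained: set[str] = set()
    for s in retained_sets:
        retained |= s.genes()
    planted = truth.light_genes
    if not retained or not planted:
        return 0.0, 0.0
    tp = len(retained & planted)
    return tp / len(retained), tp / len(planted)


def dev_mask_coverage(truth: SyntheticTruth, dev_set: set[str]) -> float:
    """Fraction of planted development genes captured by the development set."""
    planted = truth.development_genes
    if not planted:
        return 0.0
    return len(dev_set & planted) / len(planted)


def retained_fractions(rows: Sequence[MaskingRow]) -> dict[str, float]:
    """light / total per genotype (0.0 for empty within-sets)."""
    return {r.genotype: (r.light / r.total if r.total else 0.0) for r in rows}


def masking_rows_from_counts(counts: Mapping[str, Mapping[str, int]]) -> list[MaskingRow]:
    """Reconstruct masking rows by running the masking operation on synthetic
    gene sets built to match published total/development counts.

    For each genotype a within-genotype DE set with the published direction
    split is materialised with placeholder gene ids, a development set
    overlapping it by the published counts is built, and
    :func:`lightmask.contrast_masking.mask_development` recomputes the
    partition — so the retained counts and percentages are outputs of the
    actual set algebra, not transcribed numbers.
    """
    rows = []
    for genotype, c in counts.items():
        down = [f"{genotype}_dn{i}" for i in range(c["down_total"])]
        up = [f"{genotype}_up{i}" for i in range(c["up_total"])]
        members = frozenset(
            [(g, DOWN) for g in down] + [(g, UP) for g in up]
        )
        within = DirectionalGeneSet(label=genotype, q_cutoff=0.01, members=members)
        dev = set(down[: c["down_development"]]) | set(up[: c["up_development"]])
        _, row = mask_development(within, dev)
        row.genotype = genotype
        rows.append(row)
    return rows
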