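"""Development masking of light-contrast DE sets, Venn regions, concordance.

The core procedure of the pipeline: genes differentially expressed between
the developmentally most advanced genotype and *each* of the two slower
genotypes under the control light (so with no light-quality involvement) are
declared development-related; removing ("masking") them from every
genotype's within-genotype light contrast leaves the genes most likely tied
to the primary light-quality response. Membership in the development set is
by gene id only — a gene DE in both between-genotype comparisons is masked
regardless of the direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .diffexpr import DOWN, UP, DirectionalGeneSet
from .expression_qc import ValidationError


class ContrastContractError(ValueError):
    pass


class InternalConsistencyError(RuntimeError):
    pass


_DIRECTION_ALIASES = {
    "u": UP, "up": UP, "upf": UP,
    "d": DOWN, "down": DOWN, "downf": DOWN,
}


def normalize_direction(d: str) -> str:
    try:
        return _DIRECTION_ALIASES[str(d).lower()]
    except KeyError:
        raise ValidationError(f"unknown direction label {d!r}") from None


def development_set(de_a: DirectionalGeneSet, de_b: DirectionalGeneSet) -> set[str]:
    """Genes DE in *both* between-genotype control-light contrasts.

    Intersection by gene id, ignoring direction. Both inputs must come from
    the same condition and be called at the same q cutoff.
    """
    if de_a.condition is not None and de_b.condition is not None and de_a.condition != de_b.condition:
        raise ContrastContractError(
            f"between-genotype contrasts from mixed conditions: {de_a.condition!r} vs {de_b.condition!r}"
        )
    if de_a.q_cutoff != de_b.q_cutoff:
        raise ContrastContractError("between-genotype contrasts must share a q cutoff")
    return de_a.genes() & de_b.genes()


@dataclass
class MaskingRow:
    """One genotype's partition of within-genotype DE genes into
    development-attributed and light-retained counts, with direction splits."""

    genotype: str
    total: int
    development: int
    light: int
    down_total: int
    down_development: int
    down_light: int
    up_total: int
    up_development: int
    up_light: int

    def validate(self) -> None:
        triples = [
            (self.total, self.development, self.light),
            (self.down_total, self.down_development, self.down_light),
            (self.up_total, self.up_development, self.up_light),
        ]
        for total, dev, light in triples:
            if total != dev + light or min(total, dev, light) < 0:
                raise InternalConsistencyError(
                    f"{self.genotype}: total {total} != development {dev} + light {light}"
                )
        if (self.down_total + self.up_total) != self.total:
            raise InternalConsistencyError(f"{self.genotype}: direction split does not sum to total")


def mask_development(
    within: DirectionalGeneSet, dev: set[str]
) -> tuple[DirectionalGeneSet, MaskingRow]:
    """Remove development-attributed genes from a within-genotype DE set."""
    retained_members = frozenset((g, d) for g, d in within.members if g not in dev)
    retained = DirectionalGeneSet(
        label=f"{within.label}|light",
        q_cutoff=within.q_cutoff,
        members=retained_members,
        condition=within.condition,
    )
    down_total, up_total = within.n_down, within.n_up
    down_light = sum(1 for g, d in retained_members if d == DOWN)
    up_light = sum(1 for g, d in retained_members if d == UP)
    row = MaskingRow(
        genotype=within.label,
        total=len(within),
        development=len(within) - len(retained),
        light=len(retained),
        down_total=down_total,
        down_development=down_total - down_light,
        down_light=down_light,
        up_total=up_total,
        up_development=up_total - up_light,
        up_light=up_light,
    )
    row.validate()
    return retained, row


REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass
class VennPartition:
    """The 7 disjoint membership regions of three gene sets (keyed by gene id)."""

    labels: tuple[str, str, str]
    regions: dict[str, set[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": k, "n": len(self.regions[k])} for k in REGIONS]
        return pd.DataFrame(rows)


def venn_partition(
    set_a: DirectionalGeneSet, set_b: DirectionalGeneSet, set_c: DirectionalGeneSet
) -> VennPartition:
    a, b, c = set_a.genes(), set_b.genes(), set_c.genes()
    part = VennPartition(labels=(set_a.label, set_b.label, set_c.label))
    part.regions = {
        "A": a - b - c,
        "B": b - a - c,
        "C": c - a - b,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "ABC": a & b & c,
    }
    return part


@dataclass
class ConcordanceSummary:
    n_concordant: int
    n_up: int
    n_down: int
    n_discordant: int
    discordant_genes: list[str]


def classify_concordance(directions: Mapping[str, Sequence[str]]) -> ConcordanceSummary:
    """Classify genes shared by several contrasts by direction agreement.

    ``directions`` maps each gene to its per-contrast direction labels
    (any of u/d, up/down, upF/downF). A gene is concordant iff all its labels
    agree; concordant genes are split into all-up and all-down.
    """
    n_up = n_down = 0
    discordant: list[str] = []
    for gene, labels in directions.items():
        labels = list(labels)
        if not labels or any(l is None for l in labels):
            raise ValidationError(f"gene {gene!r} is missing a direction label")
        norm = [normalize_direction(l) for l in labels]
        if all(d == UP for d in norm):
            n_up += 1
        elif all(d == DOWN for d in norm):
            n_down += 1
        else:
            discordant.append(gene)
    return ConcordanceSummary(
        n_concordant=n_up + n_down,
        n_up=n_up,
        n_down=n_down,
        n_discordant=len(discordant),
        discordant_genes=sorted(discordant),
    )


def region_concordance(
    part: VennPartition, sets: Sequence[DirectionalGeneSet]
) -> dict[str, ConcordanceSummary]:
    """Direction-concordance annotation for every multi-set Venn region."""
    lookup = [s.directions() for s in sets]
    out: dict[str, ConcordanceSummary] = {}
    for region, genes in part.regions.items():
        if len(region) < 2:
            continue
        idx = [ord(ch) - ord("A") for ch in region]
        out[region] = classify_concordance(
            {g: [lookup[i][g] for i in idx] for g in genes}
        )
    return out


def masking_summary(rows: Sequence[MaskingRow]) -> pd.DataFrame:
    """Per-genotype masking summary with retained ("light") percentages (1 decimal)."""
    records = []
    for row in rows:
        row.validate()
        pct = round(100.0 * row.light / row.total, 1) if row.total else 0.0
        records.append(
            {
                "genotype": row.genotype,
                "total": row.total,
                "development": row.development,
                "light": row.light,
                "downF_total": row.down_total,
                "downF_development": row.down_development,
                "downF_light": row.down_light,
                "upF_total": row.up_total,
                "upF_development": row.up_development,
                "upF_light": row.up_light,
                "light_pct": pct,
            }
        )
    return pd.DataFrame(records)
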