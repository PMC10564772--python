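"""Expression-matrix container, TPM computation, replicate QC, and gene-id mapping.

TPM (transcripts per million) is the length-normalised abundance unit used
throughout the pipeline: per sample, ``tpm_g = 1e6 * (count_g / length_g) /
sum_h (count_h / length_h)``, so every non-degenerate sample column sums to
one million. Replicate homogeneity is assessed with Pearson correlations of
(log-transformed) per-gene abundance vectors within each genotype x condition
group, and outlying replicates are discarded with a boxplot-style fence rule
before any differential-expression contrast is formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TPM_SCALE = 1.0e6


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance container.

    Parameters
    ----------
    counts:
        Non-negative integer counts, genes as the index, samples as columns.
    gene_length_bp:
        Positive per-gene length in bp, aligned with ``counts.index``.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    _tpm: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        if self.gene_length_bp.isna().any():
            raise ValidationError("gene_length_bp missing for some genes")
        if (self.gene_length_bp <= 0).any():
            raise ValidationError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise ValidationError("gene and sample identifiers must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tpm(self) -> pd.DataFrame:
        if self._tpm is None:
            self._tpm = compute_tpm(self.counts, self.gene_length_bp)
        return self._tpm

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.gene_length_bp)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        return cls(counts=df, gene_length_bp=lengths)


def compute_tpm(counts: pd.DataFrame, gene_length_bp: pd.Series) -> pd.DataFrame:
    """Length-normalise counts to TPM; all-zero samples map to all-zero TPM."""
    lengths = pd.Series(gene_length_bp).reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValidationError("gene lengths must be positive for every gene")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    tpm = rate.div(denom.where(denom > 0, 1.0), axis=1) * TPM_SCALE
    tpm.loc[:, denom == 0] = 0.0
    return tpm


@dataclass
class ReplicateQCReport:
    """Pairwise within-group Pearson correlations for replicate QC.

    ``pairwise_r`` maps sorted sample-id pairs to r (or None when either
    vector has zero variance, in which case r is undefined and reported as
    missing rather than 0).
    """

    groups: dict[tuple[str, str], list[str]]
    pairwise_r: dict[tuple[str, str], float | None]
    transform: str

    def sample_statistic(self, sample: str, exclude: set[str] | None = None) -> float | None:
        """Mean of the sample's defined within-group correlations."""
        exclude = exclude or set()
        vals = [
            r
            for (a, b), r in self.pairwise_r.items()
            if sample in (a, b)
            and r is not None
            and not ({a, b} - {sample}) & exclude
        ]
        return float(np.mean(vals)) if vals else None

    def group_of(self, sample: str) -> tuple[str, str] | None:
        for key, members in self.groups.items():
            if sample in members:
                return key
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_i": a, "sample_j": b, "pearson_r": r}
            for (a, b), r in sorted(self.pairwise_r.items())
        ]
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "pearson_r"])


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def replicate_correlations(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    transform: str = "log2p1",
) -> ReplicateQCReport:
    """Pearson r for every within-group replicate pair.

    ``transform`` is ``"log2p1"`` (r on log2(tpm+1)) or ``"none"`` (raw TPM).
    """
    if transform not in ("log2p1", "none"):
        raise ValidationError(f"unknown transform {transform!r}")
    data = matrix.tpm
    if transform == "log2p1":
        data = np.log2(data + 1.0)
    groups: dict[tuple[str, str], list[str]] = {}
    for _, row in design.iterrows():
        groups.setdefault((row["genotype"], row["condition"]), []).append(row["sample_id"])
    pairwise: dict[tuple[str, str], float | None] = {}
    for members in groups.values():
        if len(members) < 2:
            raise ValidationError("every genotype x condition group needs >=2 samples")
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                key = tuple(sorted((a, b)))
                pairwise[key] = _pearson(data[a].to_numpy(), data[b].to_numpy())
    return ReplicateQCReport(groups=groups, pairwise_r=pairwise, transform=transform)


def flag_outlier_replicates(report: ReplicateQCReport) -> set[str]:
    """Flag replicates whose mean within-group correlation is an outlier.

    Per sample the statistic is the mean of its defined within-group Pearson
    correlations (computed among not-yet-flagged group members). The lower
    fence Q1 - 1.5*IQR is taken over the statistics of all samples pooled
    across groups; the worst sample strictly below the fence is flagged, its
    partners' statistics are recomputed without it, and the rule is repeated
    until no sample falls below the fence. A sample is only flaggable while
    its group still holds >=3 unflagged replicates, so 2-replicate groups are
    silently unflaggable.
    """
    flagged: set[str] = set()
    while True:
        stats: dict[str, float] = {}
        candidates: set[str] = set()
        for members in report.groups.values():
            active = [s for s in members if s not in flagged]
            for s in active:
                stat = report.sample_statistic(s, exclude=flagged)
                if stat is not None:
                    stats[s] = stat
                    if len(active) >= 3:
                        candidates.add(s)
        if len(stats) < 3 or not candidates:
            break
        values = np.array(list(stats.values()))
        q1, q3 = np.percentile(values, [25, 75])
        fence = q1 - 1.5 * (q3 - q1)
        below = [s for s in candidates if stats[s] < fence]
        if not below:
            break
        worst = min(below, key=lambda s: stats[s])
        flagged.add(worst)
        logger.info("flagged outlier replicate %s (statistic %.3f < fence %.3f)", worst, stats[worst], fence)
    return flagged


def load_mapping(path) -> dict[str, set[str]]:
    """Load an old_id -> new_id TSV (one pair per line) as a 1-to-many map."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            old, new = line.split("\t")[:2]
            pairs.append((old, new))
    return mapping_from_pairs(pairs)


def mapping_from_pairs(pairs: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    seen: set[tuple[str, str]] = set()
    mapping: dict[str, set[str]] = {}
    for pair in pairs:
        if pair in seen:
            raise ValidationError(f"duplicate mapping pair {pair!r}")
        seen.add(pair)
        mapping.setdefault(pair[0], set()).add(pair[1])
    return mapping


def map_gene_ids(
    table: pd.DataFrame,
    mapping: Mapping[str, set[str]] | Iterable[tuple[str, str]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Re-key a gene-indexed table through a (possibly 1-to-many) id mapping.

    Each row is emitted once per mapped new id; rows whose key is absent from
    the mapping are retained under the original key. Returns the re-keyed
    table plus a summary with mapped/unmapped/expanded row counts.
    """
    if not isinstance(mapping, Mapping):
        mapping = mapping_from_pairs(mapping)
    new_index: list[str] = []
    src_rows: list[int] = []
    n_mapped = n_unmapped = n_expanded = 0
    for pos, old in enumerate(table.index):
        targets = mapping.get(old)
        if not targets:
            new_index.append(old)
            src_rows.append(pos)
            n_unmapped += 1
        else:
            n_mapped += 1
            ordered = sorted(targets)
            if len(ordered) > 1:
                n_expanded += 1
            for new in ordered:
                new_index.append(new)
                src_rows.append(pos)
    out = table.iloc[src_rows].copy()
    out.index = pd.Index(new_index, name=table.index.name)
    summary = {"n_mapped": n_mapped, "n_unmapped": n_unmapped, "n_expanded": n_expanded}
    logger.info("map_gene_ids: %(n_mapped)d mapped, %(n_unmapped)d unmapped, %(n_expanded)d one-to-many", summary)
    return out, summary
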