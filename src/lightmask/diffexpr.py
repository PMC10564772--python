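"""Per-gene two-group differential expression with BH q-values.

The test is a Welch two-sample t on log2(TPM + 0.5) per gene; the effect
estimate ``log2fc`` is the difference of transformed group means (group B
minus group A, so for an F-vs-M contrast with A = M, positive means higher
under fluorescent light). Genes with zero variance in both groups get p = 1
when the means are equal and a machine-floor p when they differ, so the
degenerate rows stay deterministic. Multiple testing is controlled with
Benjamini-Hochberg step-up q-values, and directional DE sets are called at a
q cutoff with direction taken from the sign of the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_qc import ExpressionMatrix, ValidationError

UP = "up"
DOWN = "down"

P_FLOOR = float(np.finfo(np.float64).tiny)


class ContrastDefinitionError(ValueError):
    pass


@dataclass(frozen=True)
class DirectionalGeneSet:
    """Set of (gene_id, direction) pairs from one contrast at one q cutoff."""

    label: str
    q_cutoff: float
    members: frozenset[tuple[str, str]]
    condition: str | None = None

    def __len__(self) -> int:
        return len(self.members)

    def genes(self) -> set[str]:
        return {g for g, _ in self.members}

    def directions(self) -> dict[str, str]:
        return {g: d for g, d in self.members}

    def subset(self, direction: str) -> set[str]:
        return {g for g, d in self.members if d == direction}

    @property
    def n_up(self) -> int:
        return len(self.subset(UP))

    @property
    def n_down(self) -> int:
        return len(self.subset(DOWN))


def de_test(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Welch t-test per gene on log2(tpm + pseudocount); B minus A estimates."""
    a, b = list(group_a), list(group_b)
    if set(a) & set(b):
        raise ContrastDefinitionError("groups overlap")
    unknown = (set(a) | set(b)) - set(matrix.sample_ids)
    if unknown:
        raise ContrastDefinitionError(f"unknown samples: {sorted(unknown)}")
    if len(a) < 2 or len(b) < 2:
        raise ContrastDefinitionError("need >=2 samples per group")

    xa = np.log2(matrix.tpm[a].to_numpy() + pseudocount)
    xb = np.log2(matrix.tpm[b].to_numpy() + pseudocount)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    var_a, var_b = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)

    degenerate = (var_a == 0) & (var_b == 0)
    equal = degenerate & (mean_a == mean_b)
    p[equal] = 1.0
    p[degenerate & ~equal] = P_FLOOR
    p = np.clip(np.nan_to_num(p, nan=1.0), P_FLOOR, 1.0)
    p[equal] = 1.0

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_b - mean_a,
            "p_value": p,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    out.loc[equal, "log2fc"] = 0.0
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_qvalues(results: pd.DataFrame) -> pd.DataFrame:
    out = results.copy()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def call_de(
    results: pd.DataFrame,
    q_cutoff: float,
    label: str = "",
    condition: str | None = None,
) -> DirectionalGeneSet:
    """Directional DE set: genes with q < cutoff, direction = sign(log2fc).

    Genes with a zero estimate are never called even if q passes.
    """
    if not 0.0 < q_cutoff < 1.0:
        raise ValidationError(f"q_cutoff must be in (0, 1), got {q_cutoff}")
    if "q_value" not in results.columns:
        results = add_qvalues(results)
    hit = results[(results["q_value"] < q_cutoff) & (results["log2fc"] != 0.0)]
    members = frozenset(
        (str(g), UP if fc > 0 else DOWN) for g, fc in zip(hit.index, hit["log2fc"])
    )
    return DirectionalGeneSet(label=label, q_cutoff=q_cutoff, members=members, condition=condition)
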