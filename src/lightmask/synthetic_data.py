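"""Self-consistent toy light-quality studies with known ground truth.

The generator emulates the structure of a 3-genotype x 2-light-source barley
experiment in which plant developmental stage is confounded with the light
treatment: fluorescent light (F) delays development relative to the metal
halide control (M), and the delay grows with the genotype's light-quality
sensitivity. Counts follow a log-linear negative-binomial model

    count_{g,s} ~ NB(mean = exp(b_g + dev_slope_g * dev_stage_s
                                + ln2 * light_lfc_{g,geno(s)} * [cond(s)=F]),
                     dispersion)

so genes whose expression tracks developmental stage (``dev_slope != 0``)
show spurious M-vs-F differences within every genotype whose two light cells
sit at different stages — exactly the artifact the downstream development
masking is designed to remove. Light-responsive genes carry a genuine F-vs-M
log2 fold change, shared across genotypes with magnitudes graded by
sensitivity, or private to one genotype.

The module also emits the substrate for the downstream stages: a genome with
gene models (for promoter extraction, with a motif planted in a subset of
light-responsive promoters) and a gene->GO annotation with a small DAG in
which distinct term sets are enriched among development and light genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_qc import ExpressionMatrix

GENOTYPES = ("G_insensitive", "G_intermediate", "G_sensitive")
CONDITIONS = ("M", "F")

#: Latent developmental stage per genotype x condition cell (arbitrary units).
#: The insensitive genotype under control light is by far the most advanced
#: (it has crossed the reproductive transition, hence the largest
#: within-genotype stage gap), and fluorescent light delays every genotype,
#: in absolute stage most strongly the sensitive one.
DEFAULT_DEV_STAGE: dict[tuple[str, str], float] = {
    ("G_insensitive", "M"): 1.2,
    ("G_insensitive", "F"): 0.6,
    ("G_intermediate", "M"): 0.5,
    ("G_intermediate", "F"): 0.1,
    ("G_sensitive", "M"): 0.5,
    ("G_sensitive", "F"): -0.15,
}

#: Relative light-effect magnitude per genotype for shared light genes,
#: mirroring the graded sensitivity ranking.
LIGHT_EFFECT_SCALE = {"G_insensitive": 0.3, "G_intermediate": 0.7, "G_sensitive": 1.0}

CLASS_NULL = "null"
CLASS_DEVELOPMENT = "development"
CLASS_LIGHT_SHARED = "light_shared"
CLASS_LIGHT_SPECIFIC = "light_specific"  # stored as "light_specific:<genotype>"


class InvalidDesignError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationParams:
    """Knobs of the generative model; defaults are the package's study conditions."""

    n_genes: int = 2000
    frac_development: float = 0.10
    frac_light_shared: float = 0.05
    frac_light_specific: float = 0.02  # per genotype
    baseline_log_mean: float = 8.0  # natural-log mean count scale (null genes)
    baseline_log_sd: float = 1.0
    # development/light genes sit well below the housekeeping bulk: deep
    # libraries keep their Poisson noise low while their mass share stays a
    # few percent, so the compositional TPM denominators stay stable under
    # large planted fold changes
    effect_baseline_log_mean: float = 6.6
    effect_baseline_log_sd: float = 0.4
    dispersion: float = 0.005  # NB: var = mu + dispersion * mu^2
    dev_slope_range: tuple[float, float] = (3.0, 4.0)  # ln units per stage unit
    light_effect_range: tuple[float, float] = (2.5, 4.0)  # |log2FC| in sensitive genotype
    gene_length_range: tuple[int, int] = (500, 5000)
    motif_consensus: str = "AAATACAT"
    motif_fraction: float = 0.7  # of light-responsive genes carrying the motif
    motif_offset_range: tuple[int, int] = (-450, -60)  # TSS-relative plant window
    dev_stage: dict[tuple[str, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_development + self.frac_light_shared + 3 * self.frac_light_specific
        if total > 1.0 + 1e-12:
            raise InvalidDesignError("gene-class fractions must sum to <= 1")
        if self.dispersion <= 0:
            raise InvalidDesignError("dispersion must be > 0")
        if self.n_genes < 1:
            raise InvalidDesignError("n_genes must be >= 1")

    def stages(self) -> dict[tuple[str, str], float]:
        return dict(self.dev_stage) if self.dev_stage else dict(DEFAULT_DEV_STAGE)


@dataclass
class SyntheticTruth:
    """Ground-truth labels for a generated study."""

    gene_class: dict[str, str]
    light_effect: dict[tuple[str, str], float]  # (gene, genotype) -> signed log2FC
    dev_slope: dict[str, float]
    baseline_log: dict[str, float]
    gene_length: dict[str, int]
    planted_go_terms: dict[str, set[str]] = field(default_factory=dict)
    planted_motif: dict = field(default_factory=dict)

    def genes_of_class(self, prefix: str) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == prefix or c.startswith(prefix + ":")}

    @property
    def development_genes(self) -> set[str]:
        return self.genes_of_class(CLASS_DEVELOPMENT)

    @property
    def light_genes(self) -> set[str]:
        return self.genes_of_class(CLASS_LIGHT_SHARED) | self.genes_of_class(CLASS_LIGHT_SPECIFIC)

    def to_json(self, path) -> None:
        payload = {
            "gene_class": self.gene_class,
            "light_effect": {f"{g}|{geno}": v for (g, geno), v in self.light_effect.items()},
            "dev_slope": self.dev_slope,
            "baseline_log": self.baseline_log,
            "gene_length": self.gene_length,
            "planted_go_terms": {k: sorted(v) for k, v in self.planted_go_terms.items()},
            "planted_motif": self.planted_motif,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def generate_design(n_reps: int = 3, seed: int = 0, dev_stage=None) -> pd.DataFrame:
    """Sample design table: 3 genotypes x 2 conditions x ``n_reps`` replicates.

    ``dev_stage`` overrides the default per-cell developmental stages. The
    table is a pure function of its arguments (replicates within a cell share
    the cell's latent stage).
    """
    if n_reps < 2:
        raise InvalidDesignError("need >=2 replicates per genotype x condition cell")
    stages = dict(dev_stage) if dev_stage else dict(DEFAULT_DEV_STAGE)
    rows = []
    for geno in GENOTYPES:
        for cond in CONDITIONS:
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{geno}_{cond}{rep}",
                        "genotype": geno,
                        "condition": cond,
                        "replicate": rep,
                        "dev_stage": stages[(geno, cond)],
                    }
                )
    return pd.DataFrame(rows)


def _assign_classes(params: SimulationParams, rng: np.random.Generator) -> dict[str, str]:
    n = params.n_genes
    ids = [f"g{i:05d}" for i in range(n)]
    n_dev = int(round(params.frac_development * n))
    n_shared = int(round(params.frac_light_shared * n))
    n_spec = int(round(params.frac_light_specific * n))
    classes = dict.fromkeys(ids, CLASS_NULL)
    cursor = 0
    for gid in ids[cursor : cursor + n_dev]:
        classes[gid] = CLASS_DEVELOPMENT
    cursor += n_dev
    for gid in ids[cursor : cursor + n_shared]:
        classes[gid] = CLASS_LIGHT_SHARED
    cursor += n_shared
    for geno in GENOTYPES:
        for gid in ids[cursor : cursor + n_spec]:
            classes[gid] = f"{CLASS_LIGHT_SPECIFIC}:{geno}"
        cursor += n_spec
    return classes


def generate_counts(
    design: pd.DataFrame, params: SimulationParams
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate an NB count matrix plus its ground-truth labels."""
    rng = np.random.default_rng(params.seed)
    classes = _assign_classes(params, rng)
    ids = list(classes)

    baseline: dict[str, float] = {}
    for g in ids:
        if classes[g] == CLASS_NULL:
            baseline[g] = float(rng.normal(params.baseline_log_mean, params.baseline_log_sd))
        else:
            baseline[g] = float(
                rng.normal(params.effect_baseline_log_mean, params.effect_baseline_log_sd)
            )
    lengths = {g: int(rng.integers(params.gene_length_range[0], params.gene_length_range[1] + 1)) for g in ids}

    dev_slope: dict[str, float] = {}
    light_effect: dict[tuple[str, str], float] = {}
    lo_s, hi_s = params.dev_slope_range
    lo_e, hi_e = params.light_effect_range
    mid_stage = float(np.mean(list(params.stages().values())))
    for g in ids:
        cls = classes[g]
        if cls == CLASS_DEVELOPMENT:
            dev_slope[g] = float(rng.choice([-1.0, 1.0]) * rng.uniform(lo_s, hi_s))
            # centre the trajectory so the drawn baseline is the abundance at
            # the design's mid stage, not at stage 0 — keeps both trajectory
            # ends at quantifiable depth and the library composition stable
            baseline[g] -= dev_slope[g] * mid_stage
        elif cls == CLASS_LIGHT_SHARED:
            base = float(rng.choice([-1.0, 1.0]) * rng.uniform(lo_e, hi_e))
            for geno in GENOTYPES:
                light_effect[(g, geno)] = base * LIGHT_EFFECT_SCALE[geno]
        elif cls.startswith(CLASS_LIGHT_SPECIFIC):
            geno = cls.split(":", 1)[1]
            light_effect[(g, geno)] = float(rng.choice([-1.0, 1.0]) * rng.uniform(lo_e, hi_e))

    n_samples = len(design)
    log_mu = np.empty((len(ids), n_samples))
    base_arr = np.array([baseline[g] for g in ids])
    slope_arr = np.array([dev_slope.get(g, 0.0) for g in ids])
    for j, (_, s) in enumerate(design.iterrows()):
        eff = np.array([light_effect.get((g, s["genotype"]), 0.0) for g in ids])
        log_mu[:, j] = base_arr + slope_arr * s["dev_stage"] + np.log(2.0) * eff * (s["condition"] == "F")
    mu = np.exp(log_mu)
    if not np.all(np.isfinite(mu)):
        bad = ids[int(np.argwhere(~np.isfinite(mu))[0][0])]
        raise SimulationError(f"non-finite simulated mean for gene {bad}")

    r = 1.0 / params.dispersion  # NB size; var = mu + mu^2 / r
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=list(design["sample_id"])),
        gene_length_bp=pd.Series(lengths),
    )
    truth = SyntheticTruth(
        gene_class=classes,
        light_effect=light_effect,
        dev_slope=dev_slope,
        baseline_log=baseline,
        gene_length=lengths,
        planted_motif={"consensus": params.motif_consensus, "sites": []},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# genome + gene models

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def generate_genome_and_models(
    truth: SyntheticTruth,
    seed: int,
    fasta_path,
    gff_path,
    flank: int = 1700,
    min_flank_required: int = 1700,
    motif_fraction: float | None = None,
    motif_offset_range: tuple[int, int] = (-450, -60),
) -> tuple[str, str]:
    """Write a single-contig genome FASTA and a gene-model GFF3 for ``truth``.

    Every gene gets ``flank`` bp of clear sequence on both sides so any
    TSS-relative window within that reach can be extracted without clipping.
    The truth's motif consensus is planted, on the promoter-sense strand, at a
    recorded TSS-relative offset in a random subset of light-responsive genes;
    site records (gene, offset, strand) are appended to
    ``truth.planted_motif["sites"]``.
    """
    if flank < min_flank_required:
        raise GenerationError(
            f"flank {flank} bp is shorter than the largest requested window ({min_flank_required} bp)"
        )
    rng = np.random.default_rng(seed)
    ids = list(truth.gene_class)
    consensus = truth.planted_motif.get("consensus", "")
    if motif_fraction is None:
        motif_fraction = 0.7 if consensus else 0.0
    light = sorted(truth.light_genes)
    planted_genes: set[str] = set()
    if consensus and light and motif_fraction > 0:
        n_plant = int(round(motif_fraction * len(light)))
        planted_genes = {str(g) for g in rng.choice(light, size=n_plant, replace=False)}

    # sequential gene layout on one contig
    lengths = truth.gene_length
    total = sum(2 * flank + lengths[g] for g in ids)
    base_lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = np.array(base_lookup[rng.integers(0, 4, size=total)], dtype=np.uint8)

    records = []  # (gene, start, end, strand, tss)
    cursor = 0
    sites: list[dict] = []
    for g in ids:
        glen = lengths[g]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start = cursor + flank + 1  # 1-based
            end = start + glen - 1
            tss = start
        else:
            start = cursor + flank + 1
            end = start + glen - 1
            tss = end
        records.append((g, start, end, strand, tss))
        if g in planted_genes:
            off = int(rng.integers(motif_offset_range[0], motif_offset_range[1] + 1))
            motif_bytes = np.frombuffer(consensus.upper().encode(), dtype=np.uint8)
            if strand == "+":
                i0 = (tss - 1) + off  # 0-based genomic index of offset position
                seq[i0 : i0 + len(consensus)] = motif_bytes
            else:
                rc = np.frombuffer(reverse_complement(consensus.upper()).encode(), dtype=np.uint8)
                i1 = (tss - 1) - off  # 0-based index of offset position on forward strand
                seq[i1 - len(consensus) + 1 : i1 + 1] = rc
            sites.append({"gene": g, "offset": off, "strand": strand})
        cursor += 2 * flank + glen

    truth.planted_motif["sites"] = sites

    contig = "chr1"
    raw = seq.tobytes().decode()
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(raw), 80):
            fh.write(raw[i : i + 80] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig} 1 {len(raw)}\n")
        for g, start, end, strand, _tss in records:
            fh.write(
                f"{contig}\tlightmask_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={g}\n"
            )
    return str(fasta_path), str(gff_path)


# ---------------------------------------------------------------------------
# GO annotation

GO_ROOT = "GO:0000001"

#: static DAG skeleton: term -> (name, parents)
_GO_SKELETON: dict[str, tuple[str, tuple[str, ...]]] = {
    GO_ROOT: ("biological_process", ()),
    "GO:0000002": ("developmental process", (GO_ROOT,)),
    "GO:0000003": ("response to light stimulus", (GO_ROOT,)),
    "GO:0000004": ("metabolic process", (GO_ROOT,)),
    # planted development terms
    "GO:0000100": ("vegetative to reproductive phase transition", ("GO:0000002",)),
    "GO:0000101": ("floral organ development", ("GO:0000002",)),
    "GO:0000102": ("photoperiodism, flowering", ("GO:0000002",)),
    # planted light terms
    "GO:0000200": ("response to light quality", ("GO:0000003",)),
    "GO:0000201": ("red or far-red light signaling pathway", ("GO:0000003",)),
    "GO:0000210": ("blue light response, genotype A", ("GO:0000003",)),
    "GO:0000211": ("blue light response, genotype B", ("GO:0000003",)),
    "GO:0000212": ("blue light response, genotype C", ("GO:0000003",)),
}
_GO_BACKGROUND = {
    f"GO:00003{i:02d}": (f"metabolic subprocess {i}", ("GO:0000004",)) for i in range(10)
}

DEV_GO_TERMS = {"GO:0000100", "GO:0000101", "GO:0000102"}
LIGHT_SHARED_GO_TERMS = {"GO:0000200", "GO:0000201"}
LIGHT_SPECIFIC_GO_TERMS = {
    "G_insensitive": "GO:0000210",
    "G_intermediate": "GO:0000211",
    "G_sensitive": "GO:0000212",
}


def go_dag_dict() -> dict[str, dict]:
    """The generator's DAG as term -> {name, parents}."""
    dag = {}
    for term, (name, parents) in {**_GO_SKELETON, **_GO_BACKGROUND}.items():
        dag[term] = {"name": name, "parents": list(parents)}
    return dag


def generate_go(
    truth: SyntheticTruth,
    seed: int,
    p_in_class: float = 0.9,
    p_out_class: float = 0.02,
    p_background: float = 0.05,
) -> tuple[dict[str, set[str]], dict[str, dict]]:
    """Annotate genes with GO terms enriched in the planted classes.

    Each planted development term annotates a gene with probability
    ``p_in_class`` if the gene is a development gene and ``p_out_class``
    otherwise (analogously for the light terms); background terms annotate
    every gene with probability ``p_background``. Returns the direct
    (unpropagated) gene->terms map and the DAG dictionary.
    """
    rng = np.random.default_rng(seed)
    dag = go_dag_dict()
    dev = truth.development_genes
    shared = truth.genes_of_class(CLASS_LIGHT_SHARED)
    gene2go: dict[str, set[str]] = {g: set() for g in truth.gene_class}
    for g in truth.gene_class:
        for term in sorted(DEV_GO_TERMS):
            if rng.random() < (p_in_class if g in dev else p_out_class):
                gene2go[g].add(term)
        for term in sorted(LIGHT_SHARED_GO_TERMS):
            if rng.random() < (p_in_class if g in shared else p_out_class):
                gene2go[g].add(term)
        for geno, term in sorted(LIGHT_SPECIFIC_GO_TERMS.items()):
            specific = truth.gene_class.get(g) == f"{CLASS_LIGHT_SPECIFIC}:{geno}"
            if rng.random() < (p_in_class if specific else p_out_class):
                gene2go[g].add(term)
        for term in sorted(_GO_BACKGROUND):
            if rng.random() < p_background:
                gene2go[g].add(term)
    truth.planted_go_terms = {
        CLASS_DEVELOPMENT: set(DEV_GO_TERMS),
        CLASS_LIGHT_SHARED: set(LIGHT_SHARED_GO_TERMS),
        **{
            f"{CLASS_LIGHT_SPECIFIC}:{geno}": {term}
            for geno, term in LIGHT_SPECIFIC_GO_TERMS.items()
        },
    }
    return gene2go, dag


def write_go_map(gene2go: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene2go):
            fh.write(f"{g}\t{','.join(sorted(gene2go[g]))}\n")


def write_obo(dag: dict[str, dict], path) -> None:
    """Write an OBO subset containing only id/name/is_a stanza lines."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for term in sorted(dag):
            fh.write(f"\n[Term]\nid: {term}\nname: {dag[term]['name']}\n")
            for parent in dag[term]["parents"]:
                fh.write(f"is_a: {parent}\n")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def load_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
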