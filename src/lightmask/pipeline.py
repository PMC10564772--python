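"""Config-driven orchestration: simulate -> qc -> de -> mask -> go -> motifs.

Each stage reads the previous stage's artifacts from the run directory (or
in-memory state when run in one process), writes its outputs under fixed
filenames, and contributes a block to a single machine-readable run report
(``run_report.json``) stamped with the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrast_masking as cm
from . import diffexpr as de
from . import go_enrichment as goe
from . import motif_discovery as md
from . import synthetic_data as sd
from .expression_qc import (
    ExpressionMatrix,
    flag_outlier_replicates,
    replicate_correlations,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "de", "mask", "go", "motifs")

FILES = {
    "design": "design.tsv",
    "counts": "counts.tsv",
    "genome": "genome.fa",
    "models": "models.gff3",
    "go_map": "go_map.tsv",
    "obo": "go.obo",
    "truth": "truth.json",
    "qc_corr": "qc_correlations.tsv",
    "qc_flags": "qc_flags.tsv",
    "masking": "masking_report.tsv",
    "venn": "venn.tsv",
    "go_results": "go_enrichment.tsv",
    "report": "run_report.json",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class Diagnostic:
    level: str  # "warning" | "fatal"
    message: str


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 1
    n_reps: int = 3
    q_cutoff: float = 0.01
    q_relaxed: float = 0.05
    control: str = "M"
    transform: str = "log2p1"
    windows: list[str] = field(
        default_factory=lambda: ["-1500,+200", "-500,+200", "-500,0", "0,+200"]
    )
    k_values: list[int] = field(default_factory=lambda: [6, 7, 8])
    n_null: int = 50
    motif_alpha: float = 0.05
    min_cluster_size: int = 5
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in STAGES:
            self.stages.setdefault(s, True)
        if self.control not in sd.CONDITIONS:
            raise PipelineError(f"control condition {self.control!r} not in design conditions")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        # outdir excluded: the same analysis in two directories is the same run
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def sim_params(self) -> sd.SimulationParams:
        return sd.SimulationParams(seed=self.seed, **self.sim)


def validate_inputs(config: RunConfig) -> list[Diagnostic]:
    """Cross-check on-disk artifacts; fatal diagnostics abort the run."""
    out = Path(config.outdir)
    diags: list[Diagnostic] = []
    design_p, counts_p = out / FILES["design"], out / FILES["counts"]
    if design_p.exists() and counts_p.exists():
        design = sd.load_design(design_p)
        counts = pd.read_csv(counts_p, sep="\t", index_col="gene_id", nrows=1)
        samples = [c for c in counts.columns if c != "length"]
        missing = set(samples) - set(design["sample_id"])
        if missing:
            diags.append(Diagnostic("fatal", f"counts columns absent from design: {sorted(missing)}"))
    gff_p, fa_p = out / FILES["models"], out / FILES["genome"]
    if gff_p.exists() and fa_p.exists():
        fa_contigs = {
            line[1:].split()[0] for line in open(fa_p) if line.startswith(">")
        }
        gff_contigs = {
            line.split("\t")[0]
            for line in open(gff_p)
            if line.strip() and not line.startswith("#")
        }
        if not gff_contigs <= fa_contigs:
            diags.append(
                Diagnostic("fatal", f"gene-model contigs absent from genome: {sorted(gff_contigs - fa_contigs)}")
            )
    map_p, obo_p = out / FILES["go_map"], out / FILES["obo"]
    if map_p.exists() and obo_p.exists():
        dag = goe.parse_obo_lite(obo_p)
        gene2go = goe.load_go_map(map_p)
        unknown = {t for terms in gene2go.values() for t in terms if t not in dag}
        if unknown:
            diags.append(Diagnostic("warning", f"GO-map terms absent from DAG (skipped): {sorted(unknown)}"))
    return diags


def _within_groups(design: pd.DataFrame, genotype: str, control: str, excluded: set[str]):
    rows = design[design["genotype"] == genotype]
    a = [s for s in rows.loc[rows["condition"] == control, "sample_id"] if s not in excluded]
    b = [s for s in rows.loc[rows["condition"] != control, "sample_id"] if s not in excluded]
    return a, b


def _genotype_in_condition(design: pd.DataFrame, genotype: str, condition: str, excluded: set[str]):
    rows = design[(design["genotype"] == genotype) & (design["condition"] == condition)]
    return [s for s in rows["sample_id"] if s not in excluded]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.config_hash(), "stages": {}}

    design = matrix = truth = None

    if config.stages["simulate"]:
        params = config.sim_params()
        design = sd.generate_design(config.n_reps, seed=config.seed, dev_stage=params.dev_stage)
        matrix, truth = sd.generate_counts(design, params)
        sd.write_design(design, out / FILES["design"])
        matrix.to_tsv(out / FILES["counts"])
        sd.generate_genome_and_models(
            truth, config.seed, out / FILES["genome"], out / FILES["models"],
            motif_fraction=params.motif_fraction,
            motif_offset_range=params.motif_offset_range,
        )
        gene2go, dag_dict = sd.generate_go(truth, config.seed)
        sd.write_go_map(gene2go, out / FILES["go_map"])
        sd.write_obo(dag_dict, out / FILES["obo"])
        truth.to_json(out / FILES["truth"])
        report["stages"]["simulate"] = {
            "n_genes": len(matrix.gene_ids),
            "n_samples": len(matrix.sample_ids),
            "n_planted_motif_sites": len(truth.planted_motif["sites"]),
        }

    diags = validate_inputs(config)
    fatal = [d for d in diags if d.level == "fatal"]
    if fatal:
        raise PipelineError("; ".join(d.message for d in fatal))
    for d in diags:
        logger.warning("%s", d.message)

    needed = [s for s in ("qc", "de", "mask", "go", "motifs") if config.stages[s]]
    if needed and design is None:
        design_p, counts_p = out / FILES["design"], out / FILES["counts"]
        if not design_p.exists() or not counts_p.exists():
            raise PipelineError(f"stage {needed[0]!r}: missing design/counts artifacts in {out}")
        design = sd.load_design(design_p)
        matrix = ExpressionMatrix.from_tsv(counts_p)

    excluded: set[str] = set()
    if config.stages["qc"]:
        qc = replicate_correlations(matrix, design, transform=config.transform)
        excluded = flag_outlier_replicates(qc)
        qc.to_frame().to_csv(out / FILES["qc_corr"], sep="\t", index=False)
        pd.DataFrame({"flagged_sample": sorted(excluded)}).to_csv(
            out / FILES["qc_flags"], sep="\t", index=False
        )
        report["stages"]["qc"] = {
            "n_pairs": len(qc.pairwise_r),
            "flagged": sorted(excluded),
            "samples_kept": len(matrix.sample_ids) - len(excluded),
        }

    within_sets: dict[str, de.DirectionalGeneSet] = {}
    between_sets: dict[str, de.DirectionalGeneSet] = {}
    results: dict[str, pd.DataFrame] = {}
    if config.stages["de"]:
        if matrix is None:
            raise PipelineError("stage 'de': no expression matrix available")
        for geno in sd.GENOTYPES:
            a, b = _within_groups(design, geno, config.control, excluded)
            res = de.add_qvalues(de.de_test(matrix, a, b))
            results[f"within_{geno}"] = res
            res.to_csv(out / f"de_within_{geno}.tsv", sep="\t")
            within_sets[geno] = de.call_de(res, config.q_cutoff, label=geno)
        ref = "G_insensitive"
        for other in ("G_intermediate", "G_sensitive"):
            a = _genotype_in_condition(design, ref, config.control, excluded)
            b = _genotype_in_condition(design, other, config.control, excluded)
            res = de.add_qvalues(de.de_test(matrix, a, b))
            results[f"between_{other}"] = res
            res.to_csv(out / f"de_between_{ref}_vs_{other}.tsv", sep="\t")
            between_sets[other] = de.call_de(
                res, config.q_cutoff, label=f"{ref}_vs_{other}", condition=config.control
            )
        report["stages"]["de"] = {
            "within": {g: {"n": len(s), "up": s.n_up, "down": s.n_down} for g, s in within_sets.items()},
            "between": {g: len(s) for g, s in between_sets.items()},
        }

    retained_sets: dict[str, de.DirectionalGeneSet] = {}
    dev_genes: set[str] = set()
    mask_rows: list[cm.MaskingRow] = []
    if config.stages["mask"]:
        if not within_sets:
            raise PipelineError("stage 'mask': no DE sets available (run 'de' first)")
        dev_genes = cm.development_set(
            between_sets["G_intermediate"], between_sets["G_sensitive"]
        )
        for geno in sd.GENOTYPES:
            retained, row = cm.mask_development(within_sets[geno], dev_genes)
            retained_sets[geno] = retained
            row.genotype = geno
            mask_rows.append(row)
            pd.DataFrame(sorted(retained.members), columns=["gene_id", "direction"]).to_csv(
                out / f"retained_{geno}.tsv", sep="\t", index=False
            )
        summary = cm.masking_summary(mask_rows)
        summary.to_csv(out / FILES["masking"], sep="\t", index=False)
        part = cm.venn_partition(*[within_sets[g] for g in sd.GENOTYPES])
        conc = cm.region_concordance(part, [within_sets[g] for g in sd.GENOTYPES])
        venn_df = part.to_frame()
        venn_df["n_concordant"] = [
            conc[r].n_concordant if r in conc else None for r in venn_df["region"]
        ]
        venn_df["n_discordant"] = [
            conc[r].n_discordant if r in conc else None for r in venn_df["region"]
        ]
        venn_df.to_csv(out / FILES["venn"], sep="\t", index=False)
        report["stages"]["mask"] = {
            "n_development": len(dev_genes),
            "per_genotype": summary.set_index("genotype")[
                ["total", "development", "light", "light_pct"]
            ].to_dict("index"),
            "venn": part.counts(),
        }

    if config.stages["go"]:
        map_p, obo_p = out / FILES["go_map"], out / FILES["obo"]
        if not map_p.exists() or not obo_p.exists():
            raise PipelineError("stage 'go': missing GO map/OBO artifacts")
        if not retained_sets or not between_sets:
            raise PipelineError("stage 'go': no retained sets (run 'de' and 'mask' first)")
        dag = goe.parse_obo_lite(obo_p)
        gene2go = goe.load_go_map(map_p)
        gene2go = {g: {t for t in ts if t in dag} for g, ts in gene2go.items()}
        annotations = goe.propagate_annotations(gene2go, dag)
        kept = [s for s in matrix.sample_ids if s not in excluded]
        universe = set(matrix.tpm.loc[(matrix.tpm[kept] > 0).any(axis=1)].index)
        go_rows = []
        between_terms = {}
        for other, s in between_sets.items():
            res = goe.enrich(s.genes() & universe, universe, annotations, dag)
            between_terms[other] = {
                q: goe.significant_terms(res, q) for q in (config.q_relaxed, config.q_cutoff)
            }
        retained_terms_report = {}
        for geno in sd.GENOTYPES:
            for direction, study in (
                ("down", retained_sets[geno].subset(de.DOWN)),
                ("up", retained_sets[geno].subset(de.UP)),
                ("all", retained_sets[geno].genes()),
            ):
                res = goe.enrich(study & universe, universe, annotations, dag)
                res.insert(0, "genotype", geno)
                res.insert(1, "direction", direction)
                go_rows.append(res)
                if direction == "all":
                    kept_terms = {}
                    for q in (config.q_relaxed, config.q_cutoff):
                        within_terms = goe.significant_terms(res, q)
                        kept_terms[str(q)] = sorted(
                            goe.mask_go(
                                within_terms,
                                between_terms["G_intermediate"][q],
                                between_terms["G_sensitive"][q],
                            )
                        )
                    retained_terms_report[geno] = kept_terms
        go_all = pd.concat(go_rows, ignore_index=True)
        go_all.to_csv(out / FILES["go_results"], sep="\t", index=False)
        report["stages"]["go"] = {
            "universe": len(universe),
            "retained_terms": retained_terms_report,
        }

    if config.stages["motifs"]:
        gff_p, fa_p = out / FILES["models"], out / FILES["genome"]
        if not gff_p.exists() or not fa_p.exists():
            raise PipelineError("stage 'motifs': missing genome/gene-model artifacts")
        if not retained_sets:
            raise PipelineError("stage 'motifs': no retained sets (run 'mask' first)")
        shared = (
            retained_sets["G_intermediate"].genes() & retained_sets["G_sensitive"].genes()
        )
        dirs_int = retained_sets["G_intermediate"].directions()
        dirs_sen = retained_sets["G_sensitive"].directions()
        clusters = {
            "down": sorted(g for g in shared if dirs_int[g] == dirs_sen[g] == de.DOWN),
            "up": sorted(g for g in shared if dirs_int[g] == dirs_sen[g] == de.UP),
        }
        extractor = md.PromoterExtractor(gff_p, fa_p)
        all_genes = sorted(matrix.gene_ids)
        motif_report: dict = {"clusters": {k: len(v) for k, v in clusters.items()}, "best": {}}
        for direction, genes in clusters.items():
            if len(genes) < config.min_cluster_size:
                continue
            best = None
            for wtext in config.windows:
                window = md.PromoterWindow.parse(wtext)
                universe_seqs = extractor.extract(window, all_genes)
                cluster_seqs = {g: universe_seqs[g] for g in genes}
                for k in config.k_values:
                    background = md.background_frequencies(universe_seqs, k, both_strands=True)
                    motif = md.discover_motif(
                        cluster_seqs, background, k, alpha=config.motif_alpha, both_strands=True
                    )
                    if motif is None:
                        continue
                    emp_p, _ = md.null_cluster_significance(
                        motif.score, universe_seqs, len(genes), k,
                        n_null=config.n_null, seed=config.seed,
                        background=background, alpha=config.motif_alpha, both_strands=True,
                    )
                    motif.empirical_p = emp_p
                    entry = {
                        "window": window.label,
                        "k": k,
                        "consensus": motif.consensus,
                        "n_sites": motif.n_sites,
                        "score": motif.score,
                        "empirical_p": emp_p,
                    }
                    if best is None or (emp_p, -motif.score) < (best["empirical_p"], -best["score"]):
                        best = entry
                        md.write_meme(motif, out / f"motif_{direction}.meme", name=f"{direction}_{window.label}_k{k}")
                        md.sites_frame(motif).to_csv(
                            out / f"motif_{direction}_sites.tsv", sep="\t", index=False
                        )
            if best is not None:
                motif_report["best"][direction] = best
        report["stages"]["motifs"] = motif_report

    with open(out / FILES["report"], "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
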