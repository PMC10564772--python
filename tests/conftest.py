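import warnings

import pytest

from lightmask import synthetic_data as sd

# scipy's Welch test warns about catastrophic cancellation on the degenerate
# equal-column fixtures; the implementation handles those rows explicitly
warnings.filterwarnings("ignore", message="Precision loss occurred")


def sample_group(design, genotype, condition):
    rows = design[(design["genotype"] == genotype) & (design["condition"] == condition)]
    return list(rows["sample_id"])


@pytest.fixture(scope="session")
def default_design():
    return sd.generate_design(3, seed=1)


@pytest.fixture(scope="session")
def small_study():
    """A compact default-condition study (400 genes) shared across tests."""
    params = sd.SimulationParams(n_genes=400, seed=7)
    design = sd.generate_design(3, seed=7)
    matrix, truth = sd.generate_counts(design, params)
    return design, matrix, truth


@pytest.fixture(scope="session")
def motif_study(tmp_path_factory):
    """A genome-bearing study dense in light genes, for promoter work."""
    out = tmp_path_factory.mktemp("motif_study")
    params = sd.SimulationParams(
        n_genes=300, frac_light_shared=0.2, frac_light_specific=0.0,
        seed=1, motif_fraction=0.7,
    )
    design = sd.generate_design(3, seed=1)
    matrix, truth = sd.generate_counts(design, params)
    fasta, gff = out / "genome.fa", out / "models.gff3"
    sd.generate_genome_and_models(truth, 1, fasta, gff, motif_fraction=0.7)
    return design, matrix, truth, str(fasta), str(gff)
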