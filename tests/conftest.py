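import numpy as np
import pytest

from skintrait_pop.genotype_io import GenotypeMatrix
from skintrait_pop.panel_model import PanelVariant, TraitPanel
from skintrait_pop.synthetic_data import SimulationConfig, make_fixture_suite

FIXTURE_SEED = 11


def make_variant(rsid="rs1", chrom="1", pos=100, risk="T", other="C",
                 trait="acne", category="dermatitis", **kw) -> PanelVariant:
    return PanelVariant(rsid=rsid, chrom=chrom, pos=pos, risk_allele=risk,
                        other_allele=other, trait=trait, category=category, **kw)


def make_matrix(dosage, trait="acne", sample_ids=None, betas=None,
                impute_r2=None, direction="risk") -> GenotypeMatrix:
    """Small in-memory matrix whose columns all belong to one trait."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = [
        make_variant(rsid=f"rs{j + 1}", pos=100 + j, trait=trait,
                     beta=None if betas is None else betas[j],
                     direction=direction)
        for j in range(m)
    ]
    return GenotypeMatrix(
        sample_ids=sample_ids or [f"S{i}" for i in range(n)],
        variants=variants, dosage=dosage, impute_r2=impute_r2)


def panel_of(matrix: GenotypeMatrix, trait="acne") -> TraitPanel:
    return TraitPanel(trait=trait, category=matrix.variants[0].category,
                      variants=list(matrix.variants))


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Default synthetic study: VN (n=100) + JPT (n=96), 25 traits / 85 SNPs, F=0.05."""
    outdir = tmp_path_factory.mktemp("fixture")
    config = SimulationConfig(seed=FIXTURE_SEED)
    paths = make_fixture_suite(config, outdir, force=True)
    return config, paths


@pytest.fixture(scope="session")
def fixture_panels(fixture_suite):
    from skintrait_pop.panel_model import load_panel
    _, paths = fixture_suite
    return load_panel(paths["panel"])


@pytest.fixture(scope="session")
def fixture_matrix(fixture_suite, fixture_panels):
    from skintrait_pop.genotype_io import read_vcf_panel
    _, paths = fixture_suite
    return read_vcf_panel(paths["vcf"], fixture_panels)


@pytest.fixture(scope="session")
def fixture_samples(fixture_suite):
    from skintrait_pop.genotype_io import read_sample_table
    _, paths = fixture_suite
    return read_sample_table(paths["samples"])
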