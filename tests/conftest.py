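import pytest

from quartet_prioritizer import (
    GeneratorConfig,
    Genotype,
    GenotypeCall,
    QuartetPedigree,
    generate_quartet_scenario,
)

SAMPLES = ("FATHER", "MOTHER", "CHILD1", "CHILD2")


@pytest.fixture(scope="session")
def quartet() -> QuartetPedigree:
    return QuartetPedigree("FATHER", "MOTHER", ("CHILD1", "CHILD2"))


def make_calls(father, mother, child1, child2, gq=99, dp=40):
    """Genotype map for the standard quartet; genotypes given as Genotype enums."""
    gts = dict(zip(SAMPLES, (father, mother, child1, child2)))
    return {s: GenotypeCall(s, g, gq=gq, dp=dp) for s, g in gts.items()}


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """One modest generated scenario shared by read-only tests."""
    out = tmp_path_factory.mktemp("scenario")
    cfg = GeneratorConfig(seed=7, n_background_variants=300, n_genes=60)
    return generate_quartet_scenario(cfg, out)


HOM_REF, HET, HOM_ALT, MISSING = (
    Genotype.HOM_REF,
    Genotype.HET,
    Genotype.HOM_ALT,
    Genotype.MISSING,
)
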