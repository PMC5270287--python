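import numpy as np
import pytest

from famseq.simulate import SimulationConfig, simulate_family_cohort
from famseq.variants import AnnotatedVariant, Effect, Genotype, GenotypeMatrix, PedMember, Pedigree


def make_variant(**overrides) -> AnnotatedVariant:
    """A valid nonsynonymous variant that clears every filter stage; tests
    override single fields to probe one predicate at a time."""
    base = dict(
        chrom="chr1",
        pos=1_000_000,
        ref="G",
        alt="A",
        gene="GENE1",
        effect=Effect.NON_SYNONYMOUS_CODING,
        impact="MODERATE",
        sift=0.01,
        polyphen2_hdiv=0.99,
        phylop=2.0,
        phastcons=0.9,
        af_global=0.001,
        af_korean=0.01,
    )
    base.update(overrides)
    return AnnotatedVariant(**base)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def quartet():
    """One 2-affected / 2-unaffected nuclear family with a single variant.

    Returns (key, genotype matrix, pedigree); genotypes follow the dominant
    pattern (affected HET, unaffected HOM_REF).
    """
    ped = Pedigree(
        [
            PedMember("FAM1", "DAD", sex=1, affected=True, role="father"),
            PedMember("FAM1", "MOM", sex=2, affected=False, role="mother"),
            PedMember("FAM1", "KID1", father="DAD", mother="MOM", sex=1, affected=True),
            PedMember("FAM1", "KID2", father="DAD", mother="MOM", sex=2, affected=False),
        ]
    )
    key = ("chr1", 1_000_000, "G", "A")
    gm = GenotypeMatrix([key], ["DAD", "MOM", "KID1", "KID2"])
    for sample, call in zip(
        ["DAD", "MOM", "KID1", "KID2"],
        [Genotype.HET, Genotype.HOM_REF, Genotype.HET, Genotype.HOM_REF],
    ):
        gm.set_call(key, sample, call)
    return key, gm, ped


@pytest.fixture(scope="session")
def small_cohort():
    """A modest three-family synthetic cohort shared across tests."""
    cfg = SimulationConfig(seed=11, n_background_variants=400, n_genes=150)
    return cfg, simulate_family_cohort(cfg)


def random_variants(rng: np.random.Generator, n: int) -> list[AnnotatedVariant]:
    """Random annotated variants spanning missing values and both sides of
    every filter boundary; independent of the simulator's generative model."""
    effects = list(Effect)
    impacts = ["HIGH", "MODERATE", "LOW", "MODIFIER"]

    def maybe(value):
        return None if rng.random() < 0.2 else value

    out = []
    for i in range(n):
        out.append(
            AnnotatedVariant(
                chrom=f"chr{rng.integers(1, 23)}",
                pos=int(rng.integers(1, 10**8)),
                ref="A",
                alt="T",
                gene=f"G{rng.integers(0, 200):03d}",
                effect=effects[rng.integers(0, len(effects))],
                impact=impacts[rng.integers(0, 4)],
                sift=maybe(round(float(rng.uniform(0, 1)), 3)),
                polyphen2_hdiv=maybe(round(float(rng.uniform(0, 1)), 3)),
                phylop=maybe(round(float(rng.uniform(-3, 6)), 3)),
                phastcons=maybe(round(float(rng.uniform(0, 1)), 3)),
                af_global=maybe(round(float(rng.uniform(0, 0.05)), 4)),
                af_korean=maybe(round(float(rng.uniform(0, 0.05)), 4)),
            )
        )
    return out
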