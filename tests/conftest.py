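import numpy as np
import pytest

from hervwha.catalog import Region, RegionCatalog
from hervwha.coverage import AlignedRead
from hervwha.simulate import CohortSpec, SampleSpec


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_catalog(rng) -> RegionCatalog:
    """Three HERV loci (1000/950/300 nt) and one host gene, windows of 100."""
    regions = [
        Region("HERV001", "herv", "chr5", 1000, 2000, "+", random_sequence(1000, rng)),
        Region("HERV002", "herv", "chr5", 3000, 3950, "+", random_sequence(950, rng)),
        Region("HERV003", "herv", "chr5", 5000, 5300, "-", random_sequence(300, rng)),
        Region("JAKMIP2", "host_gene", "chr5", 7000, 8200, "+", random_sequence(1200, rng)),
    ]
    return RegionCatalog(regions, window_length=100)


def make_read(
    region_id: str = "HERV001",
    pos: int = 0,
    length: int = 100,
    n_mismatches: int = 0,
    barcode: str = "AAAA",
    read_id: str = "r0",
    mismatch_positions: tuple[int, ...] | None = None,
) -> AlignedRead:
    if mismatch_positions is None:
        mismatch_positions = tuple(range(pos, pos + n_mismatches))
    return AlignedRead(
        read_id=read_id,
        region_id=region_id,
        pos=pos,
        aligned_length=length,
        n_matches=length - n_mismatches,
        barcode=barcode,
        mismatch_positions=mismatch_positions,
    )


def small_cohort_spec(seed: int = 7, **overrides) -> CohortSpec:
    """3 controls + 3 PASC over 4 loci; HERV001 robustly expressed in PASC."""
    samples = tuple(
        [SampleSpec(sample_id=f"C{i}", cohort="control", expressed={}) for i in range(3)]
        + [
            SampleSpec(
                sample_id=f"P{i}",
                cohort="PASC",
                expressed={"HERV001": (12, 6.0), "HERV002": (5, 4.0)},
            )
            for i in range(3)
        ]
    )
    defaults = dict(
        n_loci=4, locus_length=1500, n_host_genes=1, samples=samples, seed=seed
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)
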