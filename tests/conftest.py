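import numpy as np
import pytest

import fapcore as fc


def make_segmentation(period: int, n_repeats: int = 3, linker: int = 0) -> fc.RepeatSegmentation:
    """Contiguous or linker-separated repeat segmentation over a poly-A sequence."""
    repeats, pos = [], linker
    for _ in range(n_repeats):
        repeats.append((pos + 1, pos + period))
        pos += period + linker
    seq = "A" * max(pos, repeats[-1][1])
    return fc.RepeatSegmentation(sequence=seq, repeats=repeats, repeat_length=period)


@pytest.fixture(scope="session")
def fapc_model():
    """Idealized two-sided FapC-like fiber core: three 37-residue rungs."""
    seg = make_segmentation(37)
    rolemap = fc.assign_roles(seg, "two_sided", arc_length=5)
    return fc.build_solenoid(rolemap)


@pytest.fixture(scope="session")
def csga_model():
    """CsgA-like two-sided core: three 22-residue rungs, 9+9 strands."""
    seg = make_segmentation(22)
    rolemap = fc.assign_roles(seg, "two_sided", arc_length=2)
    return fc.build_solenoid(rolemap)


@pytest.fixture(scope="session")
def fapc_trimer(fapc_model):
    return fc.stack_monomers(fapc_model, 3)


def random_hits(rng, n_max=20, n_contigs=2, coord_span=40_000):
    """Random homolog hit fixture for oracle-equivalence tests."""
    n = int(rng.integers(0, n_max + 1))
    hits = []
    for k in range(n):
        start = int(rng.integers(1, coord_span))
        length = int(rng.integers(200, 2000))
        hits.append(fc.HomologHit(
            protein_id=f"p{k}",
            component=fc.COMPONENTS[int(rng.integers(6))],
            assembly_id="asm",
            contig_id=f"ctg{int(rng.integers(n_contigs))}",
            start=start,
            end=start + length - 1,
            strand="+" if rng.random() < 0.5 else "-",
        ))
    return hits
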