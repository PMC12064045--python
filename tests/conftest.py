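import numpy as np
import pandas as pd
import pytest

from mirmodule.catalog import MatureMiRNA, apply_families
from mirmodule.simulate import make_fixture


@pytest.fixture(scope="session")
def example_mirna() -> MatureMiRNA:
    """21-nt miRNA whose seed-match strings are easy to verify by hand:
    revcomp(m2-m8) = TGGACTG, revcomp(m2-m7) = GGACTG."""
    return MatureMiRNA("miR-ex", "UCAGUCCAUGGAUGUCAGUCC")


@pytest.fixture(scope="session")
def module_mirnas() -> list[MatureMiRNA]:
    """Small planted module: 6 miRNAs, one shared-seed pair -> 5 families."""
    rng = np.random.default_rng(123)
    seqs = []
    while len(seqs) < 6:
        seq = "".join(rng.choice(list("ACGU"), size=21))
        if all(seq[1:8] != s[1:8] for s in seqs):
            seqs.append(seq)
    # make the last one share the seed of the first (different 3' half)
    seqs[5] = seqs[0][:8] + seqs[5][8:]
    return apply_families(
        [MatureMiRNA(f"miR-t{i + 1}", s) for i, s in enumerate(seqs)]
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Full synthetic input bundle (seed 0), shared across the session."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture(outdir, seed=0)


def random_utr(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_mirna(rng: np.random.Generator, name: str = "miR-r", length: int = 21) -> MatureMiRNA:
    return MatureMiRNA(name, "".join(rng.choice(list("ACGU"), size=length)))
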