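import numpy as np
import pytest
from hypothesis import settings

from mirvar.reference_io import load_reference

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_reference(tmp_path):
    """A two-species toy reference loaded through the FASTA reader.

    sim-miR-1 sits at [4, 12) of sim-mir-1 with 4 nt of flank either side;
    sim-miR-2 at [3, 11) of sim-mir-2.  hsa-miR-9 has no same-species hairpin.
    """
    mature = tmp_path / "mature.fa"
    hairpin = tmp_path / "hairpin.fa"
    mature.write_text(
        ">sim-miR-1\nACGTACGT\n"
        ">sim-miR-2\nTTGGCCAA\n"
        ">hsa-miR-9\nGGGGCCCC\n"
    )
    hairpin.write_text(
        ">sim-mir-1\nGGCCACGTACGTTTAA\n"
        ">sim-mir-2\nAAATTGGCCAATTTGG\n"
    )
    return load_reference(mature, hairpin, species_prefixes=["sim", "hsa"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
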