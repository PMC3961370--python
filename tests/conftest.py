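import numpy as np
import pytest

from fastfuse.pixel_fret import ChannelImage, FretImageSet
from fastfuse.stoichiometry import StoichModel


@pytest.fixture(scope="session")
def reported_model() -> StoichModel:
    """The best-fit cluster/site parameters reported for the p10 titration."""
    return StoichModel(n=8.74, s=5.17)


def make_imageset(donor, acceptor, fret, cell_id="cell", condition="") -> FretImageSet:
    return FretImageSet(
        donor=ChannelImage(np.asarray(donor, dtype=float), "donor"),
        acceptor=ChannelImage(np.asarray(acceptor, dtype=float), "acceptor"),
        fret=ChannelImage(np.asarray(fret, dtype=float), "fret"),
        cell_id=cell_id,
        condition=condition,
    )


@pytest.fixture
def uniform_set():
    shape = (32, 32)
    return make_imageset(
        np.full(shape, 100.0), np.full(shape, 100.0), np.full(shape, 100.0)
    )
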