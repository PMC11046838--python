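import numpy as np
import pytest
from hypothesis import settings

from gammafoci import BinnedTrack, GenomeModel

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def small_genome() -> GenomeModel:
    return GenomeModel(("chr1",), (30_000,), 150)


@pytest.fixture
def make_track():
    """Build a BinnedTrack from a per-chromosome dict of count lists."""

    def _make(genome: GenomeModel, counts: dict, bin_size: int | None = None) -> BinnedTrack:
        arrays = {c: np.asarray(v, dtype=float) for c, v in counts.items()}
        return BinnedTrack(genome, arrays, bin_size=bin_size)

    return _make


@pytest.fixture
def flat_tracks(small_genome, make_track):
    """Identical flat treatment/control tracks (10 tags per bin)."""
    n = small_genome.n_bins("chr1")
    t = make_track(small_genome, {"chr1": np.full(n, 10.0)})
    c = make_track(small_genome, {"chr1": np.full(n, 10.0)})
    return t, c
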