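import numpy as np
import pytest

from mitogeodiv import Alignment, SampleRecord


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(("a", "b", "c"), ("ACGT", "ACGA", "ACCA"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_record(
    id: str,
    lat: float,
    lon: float,
    basin: str = "basin01",
    phylogroup: str = "A",
    seq_name: str | None = None,
) -> SampleRecord:
    return SampleRecord(
        id=id,
        lat=lat,
        lon=lon,
        basin=basin,
        phylogroup=phylogroup,
        seq_name=seq_name if seq_name is not None else id,
    )


def random_alignment(
    rng: np.random.Generator,
    n: int,
    length: int,
    missing_frac: float = 0.0,
    gap_frac: float = 0.0,
) -> list[str]:
    """Random rows over ACGT with optional N / '-' contamination."""
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, (n, length))]
    if missing_frac:
        mat[rng.random((n, length)) < missing_frac] = "N"
    if gap_frac:
        mat[rng.random((n, length)) < gap_frac] = "-"
    return ["".join(row) for row in mat]
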