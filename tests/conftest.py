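import pytest

from ratipd import PayoffMatrix, TimingModel


@pytest.fixture
def matrix1() -> PayoffMatrix:
    """First-experiment matrix: 1/2 pellets for R/T, 4/8 s timeout for P/S."""
    return PayoffMatrix(p_r=1, p_t=2, p_p=4, p_s=8, label="1-2-4-8")


@pytest.fixture
def standard_matrix() -> PayoffMatrix:
    """Classic all-pellet matrix (T=6, R=4, P=1, S=0)."""
    return PayoffMatrix(p_r=4, p_t=6, p_p=1, p_s=0, label="standard",
                        all_pellet_mode=True)


@pytest.fixture
def timing() -> TimingModel:
    return TimingModel()
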