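import pytest

from cropgame import ModelParams


@pytest.fixture
def base_params() -> ModelParams:
    """The standard worked example: K=10, a=b=1, theta=2, p=0.4, p1=0, p2=0.8."""
    return ModelParams(K=10, theta=2, a=1, b=1, p=0.4, p1=0.0, p2=0.8)


@pytest.fixture
def losing_params() -> ModelParams:
    """p2 = 0.5 makes every mixture a convex combination of values <= 0.5."""
    return ModelParams(K=10, theta=2, a=1, b=1, p=0.4, p1=0.0, p2=0.5)
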