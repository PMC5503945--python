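import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def payload_3633() -> bytes:
    """A fixed pseudo-random input of the reference size (3,633 bytes)."""
    rng = np.random.default_rng(42)
    return rng.integers(0, 256, 3633, dtype=np.uint8).tobytes()


@pytest.fixture(scope="session")
def encoded_3633(payload_3633):
    """Blocks + sidecar for the reference input, shared across tests."""
    from dnastore.codec import encode_file, make_sidecar

    blocks = encode_file(payload_3633)
    sidecar = make_sidecar(blocks, len(payload_3633) * 8)
    return blocks, sidecar


@pytest.fixture(scope="session")
def random_block() -> str:
    """One realistic (balanced, addressed) 1,000-base block."""
    from dnastore.codec import encode_file

    rng = np.random.default_rng(7)
    data = rng.integers(0, 256, 216, dtype=np.uint8).tobytes()
    return encode_file(data)[0].sequence
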