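import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def write_csv(tmp_path):
    """Write a CSV file under tmp_path from a header and rows; returns the path."""

    def _write(name, header, rows):
        path = tmp_path / name
        lines = [",".join(header)] + [",".join(str(v) for v in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
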