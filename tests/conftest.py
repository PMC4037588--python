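import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def make_scan():
    """Build a centroided MS1 Scan from (mz, intensity) pairs."""
    from proteo18.cluster import Scan

    def _make(scan_number, peaks, rt=None, ms_level=1):
        peaks = sorted(peaks)
        return Scan(
            scan_number=scan_number,
            retention_time=float(scan_number) if rt is None else rt,
            mz=np.array([p[0] for p in peaks], dtype=float),
            intensity=np.array([p[1] for p in peaks], dtype=float),
            ms_level=ms_level,
        )

    return _make
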