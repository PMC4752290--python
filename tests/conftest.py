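import struct

import matplotlib
import numpy as np
import pytest
from hypothesis import settings

matplotlib.use("Agg")

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_minimal_edf(path, data_uv, fs, labels):
    """Write a single-record EDF file (synthetic fixture, built in-test).

    ``data_uv`` is channels x samples in microvolts; all samples fit one
    data record.  Enough of the format for readers to recover the signal
    to 16-bit precision.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    ns, n_samp = data_uv.shape
    assert ns == len(labels)
    duration = n_samp / fs
    pmin = float(min(data_uv.min(), -1.0))
    pmax = float(max(data_uv.max(), 1.0))
    dmin, dmax = -32768, 32767

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate 01-JAN-2020 X X X", 80),
            f("01.01.20", 8),
            f("00.00.00", 8),
            f(256 * (ns + 1), 8),
            f("", 44),
            f(1, 8),
            f(f"{duration:g}", 8),
            f(ns, 4),
        ]
    )
    for width, values in (
        (16, labels),
        (80, [""] * ns),
        (8, ["uV"] * ns),
        (8, [f"{pmin:.1f}"] * ns),
        (8, [f"{pmax:.1f}"] * ns),
        (8, [str(dmin)] * ns),
        (8, [str(dmax)] * ns),
        (80, [""] * ns),
        (8, [str(n_samp)] * ns),
        (32, [""] * ns),
    ):
        hdr += b"".join(f(v, width) for v in values)
    scaled = np.round(
        (data_uv - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(scaled.tobytes())
    return path
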