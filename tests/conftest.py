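"""Shared fixtures: small synthetic montages, prototypes and file writers."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from mstates import make_montage, make_prototype_maps


@pytest.fixture(scope="session")
def montage64() -> np.ndarray:
    return make_montage(64, seed=1)


@pytest.fixture(scope="session")
def protos5(montage64):
    return make_prototype_maps(montage64, K=5, seed=1, max_abs_corr=0.6)


@pytest.fixture(scope="session")
def montage32() -> np.ndarray:
    return make_montage(32, seed=2)


def write_minimal_edf(path: Path, data_uv: np.ndarray, fs: float) -> None:
    """Write a bare-bones EDF file (synthetic fixture, int16 quantized).

    One 1-second data record per second of signal; physical range ±200 µV.
    """
    n_ch, n_samp = data_uv.shape
    rec_dur = 1.0
    spr = int(round(fs * rec_dur))
    assert n_samp % spr == 0
    n_rec = n_samp // spr
    pmin, pmax = -200.0, 200.0
    dmin, dmax = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2020", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8), pad("", 44),
        pad(str(n_rec), 8), pad(str(rec_dur), 8), pad(str(n_ch), 4),
    ])
    fields = [
        ("label", 16, [f"EEG ch{i:02d}" for i in range(n_ch)]),
        ("transducer", 80, [""] * n_ch),
        ("dim", 8, ["uV"] * n_ch),
        ("pmin", 8, [str(pmin)] * n_ch),
        ("pmax", 8, [str(pmax)] * n_ch),
        ("dmin", 8, [str(dmin)] * n_ch),
        ("dmax", 8, [str(dmax)] * n_ch),
        ("prefilter", 80, [""] * n_ch),
        ("spr", 8, [str(spr)] * n_ch),
        ("reserved", 32, [""] * n_ch),
    ]
    for _, width, values in fields:
        header += b"".join(pad(v, width) for v in values)

    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data_uv - pmin) * gain + dmin), dmin, dmax).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(digital[c, r * spr:(r + 1) * spr].tobytes())


@pytest.fixture()
def edf_file(tmp_path) -> tuple[Path, np.ndarray, float]:
    rng = np.random.default_rng(7)
    fs = 500.0
    data = rng.normal(scale=20.0, size=(19, int(10 * fs)))
    path = tmp_path / "toy.edf"
    write_minimal_edf(path, data, fs)
    return path, data, fs
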