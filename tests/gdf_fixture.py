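"""Minimal synthetic GDF 1.25 writer used as a round-trip test fixture.

This is a *synthetic* stand-in for a real 4-class motor-imagery recording:
just enough of the GDF 1.x container (fixed header, per-channel headers,
int16 data records, mode-1 event table) to exercise the GDF reading path.
Written at test time; no binary fixture is stored in the repository.
"""

from __future__ import annotations

import struct

import numpy as np


def write_gdf(path, data_uv: np.ndarray, fs: int, events) -> None:
    """Write ``data_uv`` (channels x samples, microvolts) as GDF 1.25.

    ``events`` is a list of (sample_index_0based, type_code); cue codes for
    the four imagery classes are 769..772.
    """
    n_ch, n_samp = data_uv.shape
    with open(path, "wb") as f:
        f.write(b"GDF 1.25")
        f.write(b"X X".ljust(80))
        f.write(b"synthetic motor imagery".ljust(80))
        f.write(b"2024010112000000")
        header_nbytes = 256 + n_ch * 256
        f.write(struct.pack("<q", header_nbytes))
        f.write(b"\x00" * 24)          # equipment / hospital / technician ids
        f.write(b"\x00" * 20)          # reserved
        f.write(struct.pack("<q", 1))  # one data record holding everything
        f.write(struct.pack("<II", n_samp, int(fs)))
        f.write(struct.pack("<I", n_ch))
        for i in range(n_ch):
            f.write(f"EEG-{i + 1}".encode().ljust(16))
        f.write(b" " * 80 * n_ch)      # transducer type
        for _ in range(n_ch):
            f.write(b"uV".ljust(8))
        f.write(np.full(n_ch, -3276.8, "<f8").tobytes())   # physical min
        f.write(np.full(n_ch, 3276.7, "<f8").tobytes())    # physical max
        f.write(np.full(n_ch, -32768, "<i8").tobytes())    # digital min
        f.write(np.full(n_ch, 32767, "<i8").tobytes())     # digital max
        f.write(b" " * 80 * n_ch)      # prefiltering
        f.write(np.full(n_ch, n_samp, "<i4").tobytes())    # samples per record
        f.write(np.full(n_ch, 3, "<i4").tobytes())         # GDF type 3 = int16
        f.write(b"\x00" * 32 * n_ch)
        dig = np.clip(np.round(data_uv * 10.0), -32768, 32767).astype("<i2")
        f.write(dig.tobytes())
        f.write(struct.pack("<B", 1))  # event table mode 1
        sr = int(fs)
        f.write(bytes([sr & 255, (sr >> 8) & 255, (sr >> 16) & 255]))
        f.write(struct.pack("<I", len(events)))
        f.write(np.array([p + 1 for p, _ in events], "<u4").tobytes())
        f.write(np.array([t for _, t in events], "<u2").tobytes())
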