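"""8-bit gray image files: PGM (P2 ascii / P5 binary) and optional PNG.

Histogram row 0 holds the *lowest* signal; image files are written with rows
flipped so low signal sits at the bottom of the displayed picture. Reading
flips back, so write -> read round-trips the in-memory array.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_pgm", "read_pgm", "write_png"]


def write_pgm(path, pixels: np.ndarray, binary: bool = False) -> None:
    px = np.asarray(pixels)
    if px.min(initial=0) < 0 or px.max(initial=0) > 255:
        raise ValueError("PGM pixels must be in [0, 255]")
    disp = px[::-1]  # display orientation: row 0 at the bottom
    h, w = disp.shape
    if binary:
        with open(path, "wb") as fh:
            fh.write(f"P5\n{w} {h}\n255\n".encode())
            fh.write(disp.astype(np.uint8).tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(f"P2\n{w} {h}\n255\n")
            for row in disp:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_pgm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        buf = fh.read()
    magic = buf[:2]
    if magic not in (b"P2", b"P5"):
        raise ValueError(f"{path}: not a PGM file")
    # tokenize header: magic, width, height, maxval (comments start with '#')
    tokens: list[bytes] = []
    i = 2
    while len(tokens) < 3 and i < len(buf):
        c = buf[i : i + 1]
        if c == b"#":
            while i < len(buf) and buf[i : i + 1] != b"\n":
                i += 1
        elif c.isspace():
            i += 1
        else:
            j = i
            while j < len(buf) and not buf[j : j + 1].isspace():
                j += 1
            tokens.append(buf[i:j])
            i = j
    w, h, maxval = (int(t) for t in tokens)
    if maxval > 255:
        raise ValueError(f"{path}: only 8-bit PGM supported")
    if magic == b"P5":
        data = np.frombuffer(buf[i + 1 : i + 1 + w * h], dtype=np.uint8)
    else:
        data = np.array(buf[i:].split(), dtype=np.int64)
    if data.size != w * h:
        raise ValueError(f"{path}: pixel count does not match header")
    disp = data.reshape(h, w).astype(np.int64)
    return disp[::-1]


def write_png(path, pixels: np.ndarray) -> None:
    from PIL import Image

    disp = np.asarray(pixels)[::-1].astype(np.uint8)
    Image.fromarray(disp, mode="L").save(path)
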