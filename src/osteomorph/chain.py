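"""Silhouette binarization and Freeman chain coding.

The 2D pipeline starts from a silhouette image of the bone: the image
is thresholded (Otsu), the largest connected foreground component kept
and its holes filled, and the outer boundary traced with
Moore-neighbour tracing into an 8-direction Freeman chain code.

Coordinate convention: chain codes live in a right-handed frame with
``x = column`` and ``y = -row`` (y up), direction 0 = +x, numbering
counterclockwise (1 = up-right diagonal, 2 = up, ...).  Boundaries are
emitted counterclockwise in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["ChainCode", "binarize", "trace_chain", "chain_to_contour",
           "read_chain_file", "write_chain_file"]

# displacement (dx, dy with y up) for each Freeman direction
_FREEMAN = np.array([(1, 0), (1, 1), (0, 1), (-1, 1),
                     (-1, 0), (-1, -1), (0, -1), (1, -1)])
_CODE_OF = {tuple(v): i for i, v in enumerate(_FREEMAN)}


@dataclass
class ChainCode:
    """Closed Freeman 8-direction chain code of one outline."""

    start_pixel: tuple[int, int]          # (row, col) of the first boundary pixel
    codes: np.ndarray                     # sequence over {0..7}
    name: str = ""

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.size < 4:
            raise ValueError("chain code must have length >= 4")
        if np.any((self.codes < 0) | (self.codes > 7)):
            raise ValueError("chain codes must be in 0..7")
        disp = _FREEMAN[self.codes].sum(axis=0)
        if disp[0] != 0 or disp[1] != 0:
            raise ValueError("chain code is not closed (nonzero net displacement)")

    def __len__(self) -> int:
        return int(self.codes.size)


def binarize(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold a single-channel image into a foreground mask.

    The foreground is the *bright* side of the threshold: strictly
    above an automatic Otsu value (scikit-image convention), or
    ``>=`` a user-supplied one.  Only the largest 8-connected component
    is kept and its interior holes are filled.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("binarize expects a single-channel 2D image")
    if threshold is None:
        vals = np.unique(img)
        if vals.size < 2:
            raise ValueError("image has a single gray value; no foreground found")
        mask = img > threshold_otsu(img)
    else:
        mask = img >= threshold
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def trace_chain(mask: np.ndarray, name: str = "") -> ChainCode:
    """Trace the outer boundary of a mask into a closed Freeman chain.

    Moore-neighbour tracing with Jacob's stopping criterion; the start
    pixel is the top-most, then left-most foreground pixel.  The pixel
    sequence is oriented counterclockwise (positive signed area in the
    x = col / y = -row frame) before encoding.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 3:
        raise ValueError("degenerate region: need at least 3 foreground pixels")
    rows, cols = np.nonzero(mask)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))

    # Moore neighbourhood in clockwise order starting west (row, col offsets)
    nbr = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]

    def fg(p):
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    def step(cur, prev):
        """Next boundary pixel, scanning clockwise from the backtrack."""
        k0 = nbr.index((prev[0] - cur[0], prev[1] - cur[1]))
        for j in range(1, 9):
            off = nbr[(k0 + j) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if fg(cand):
                back = nbr[(k0 + j - 1) % 8]
                return cand, (cur[0] + back[0], cur[1] + back[1])
        raise ValueError("degenerate region: isolated pixel")

    boundary = [start]
    cur, prev = start, (start[0], start[1] - 1)  # west of start is background
    first_move = None
    while True:
        nxt, prev = step(cur, prev)
        if first_move is None:
            first_move = nxt
        elif cur == start and nxt == first_move:
            boundary.pop()  # drop the duplicated start appended on re-entry
            break
        boundary.append(nxt)
        cur = nxt
        if len(boundary) > 4 * mask.size:
            raise RuntimeError("boundary tracing failed to terminate")

    pix = np.array(boundary)
    # orient counterclockwise in the (x=col, y=-row) frame
    x, y = pix[:, 1].astype(float), -pix[:, 0].astype(float)
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        pix = pix[::-1]
        pix = np.roll(pix, 1, axis=0)  # keep the start pixel first

    closed = np.vstack([pix, pix[:1]])
    d = np.diff(closed, axis=0)                   # (drow, dcol)
    codes = [_CODE_OF[(int(dc), int(-dr))] for dr, dc in d]
    return ChainCode(start_pixel=tuple(int(v) for v in pix[0]),
                     codes=np.array(codes), name=name)


def chain_to_contour(chain: ChainCode) -> np.ndarray:
    """Decode a chain to polygon vertices in the (x, y-up) frame."""
    steps = _FREEMAN[chain.codes]
    r0, c0 = chain.start_pixel
    pts = np.vstack([[0, 0], np.cumsum(steps[:-1], axis=0)]).astype(float)
    pts[:, 0] += c0
    pts[:, 1] += -r0
    return pts


def write_chain_file(path: str | Path, chains: list[ChainCode]) -> None:
    """Write chains in the plain-text record format ``id length digits``."""
    with open(path, "w") as fh:
        for ch in chains:
            digits = "".join(str(int(c)) for c in ch.codes)
            fh.write(f"{ch.name or 'outline'} {len(ch)} {digits}\n")


def read_chain_file(path: str | Path) -> list[ChainCode]:
    """Read chain-code records (``id length digits``, one per line)."""
    chains = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            name, length, digits = line.split()
            length = int(length)
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed chain record") from exc
        if len(digits) != length:
            raise ValueError(f"{path}:{ln}: length field {length} != {len(digits)} digits")
        codes = np.array([int(c) for c in digits], dtype=np.int8)
        chains.append(ChainCode(start_pixel=(0, 0), codes=codes, name=name))
    return chains
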