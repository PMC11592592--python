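"""Bar-image and bond-vector codec for stem-loop RNA.

A structured RNA is drawn on a 100x25 pixel grid with 5 one-hot color
channels (A, C, G, U, GAP). Each of the 100 columns holds at most two
bars: one attached to the top edge (5' arm, read left to right) and one to
the bottom edge (3' arm, read right to left). Paired nucleotides share a
column; an unpaired stem nucleotide faces a 2-px GAP bar; terminal-loop
nucleotides are drawn one per column at the apex, the first half on the
top row and the rest on the bottom row. Bar length encodes bond strength:

* strong (Watson-Crick A-U / G-C) pair  -> both bars 3 px
* weak pair (e.g. G-U) or unpaired      -> 4 px, +1 px per additional
  consecutive weak/none column in the current run, capped at 12 px
* GAP                                   -> always 2 px

Strong bonds also set position i of the length-100 binary bond vector m.
The mapping is exactly invertible; :func:`decode_image` recovers sequence
and dot-bracket from any well-formed image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import StructuredRNA, is_single_stem_loop, parse_pairs

__all__ = [
    "N_COLS", "N_ROWS", "N_CHANNELS", "COLORS", "HEIGHTS",
    "Column", "BarSpec",
    "align_arms", "classify_bond", "bar_lengths",
    "encode_image", "decode_image", "bars_from_image", "image_bond_vector",
    "image_to_png",
]

N_COLS = 100
N_ROWS = 25
N_CHANNELS = 5
COLORS = ("A", "C", "G", "U", "GAP")
_COLOR_INDEX = {c: i for i, c in enumerate(COLORS)}

STRONG_LEN = 3
GAP_LEN = 2
WEAK_BASE = 4
MAX_BAR = 12
# discrete bar-height vocabulary shared with the VAE decoder
HEIGHTS = (0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12)
HEIGHT_CLASS = {h: i for i, h in enumerate(HEIGHTS)}

_WC = {frozenset(("A", "U")), frozenset(("G", "C"))}


@dataclass(frozen=True)
class Column:
    """One aligned column: top entry, bottom entry, bond class.

    Entries are a nucleotide letter, ``"GAP"`` or ``None`` (no bar)."""

    top: str | None
    bottom: str | None
    bond: str  # strong | weak | none


@dataclass(frozen=True)
class BarSpec:
    column: int
    row_side: str  # top | bottom
    color: str
    length: int

    def __post_init__(self):
        if self.color == "GAP" and self.length != GAP_LEN:
            raise ValueError("GAP bars have length exactly 2")
        if not 0 <= self.length <= MAX_BAR:
            raise ValueError(f"bar length {self.length} outside [0, {MAX_BAR}]")


def classify_bond(top: str | None, bottom: str | None) -> str:
    """strong for Watson-Crick pairs, weak for any other base pair,
    none when either side is a gap / absent."""
    if top in (None, "GAP") or bottom in (None, "GAP"):
        return "none"
    return "strong" if frozenset((top, bottom)) in _WC else "weak"


def align_arms(rna: StructuredRNA) -> list[Column]:
    """Align the two arms of a single stem-loop into image columns.

    The 5' arm runs left to right on the top row, the 3' arm right to left
    on the bottom row; paired positions share a column, unpaired stem
    positions face a GAP, and the terminal loop is split between the rows
    in disjoint apex columns. Raises on branched structures or alignments
    wider than 100 columns.
    """
    if not is_single_stem_loop(rna.structure):
        raise ValueError(f"{rna.id}: structure is not a single stem-loop")
    n = len(rna)
    pairs = parse_pairs(rna.structure)
    columns: list[Column] = []

    if not pairs:
        columns = [Column(nt, "GAP", "none") for nt in rna.sequence]
    else:
        pair_of = dict(pairs)
        i_inner, j_inner = pairs[-1]
        a, b = 0, n - 1
        while a <= i_inner or b >= j_inner:
            if pair_of.get(a) == b:
                columns.append(Column(rna.sequence[a], rna.sequence[b],
                                      classify_bond(rna.sequence[a], rna.sequence[b])))
                a += 1
                b -= 1
            elif a <= i_inner and rna.structure[a] == ".":
                columns.append(Column(rna.sequence[a], "GAP", "none"))
                a += 1
            elif b >= j_inner and rna.structure[b] == ".":
                columns.append(Column("GAP", rna.sequence[b], "none"))
                b -= 1
            else:  # pragma: no cover - excluded by the stem-loop check
                raise ValueError(f"{rna.id}: crossing pairs in structure")
        loop = [rna.sequence[k] for k in range(a, b + 1)]
        half = (len(loop) + 1) // 2
        columns += [Column(nt, None, "none") for nt in loop[:half]]
        # bottom half laid right-to-left so the 3'-ward read stays in order
        columns += [Column(None, nt, "none") for nt in reversed(loop[half:])]

    if len(columns) > N_COLS:
        raise ValueError(
            f"{rna.id}: aligned structure spans {len(columns)} columns "
            f"(limit {N_COLS})"
        )
    return columns


def bar_lengths(columns: list[Column]) -> list[tuple[int, int]]:
    """Per column (top_len, bottom_len); 0 where there is no bar."""
    out: list[tuple[int, int]] = []
    run = 0
    for col in columns:
        if col.bond == "strong":
            run = 0
            out.append((STRONG_LEN, STRONG_LEN))
            continue
        weak_len = min(WEAK_BASE + run, MAX_BAR)
        run += 1
        top = 0 if col.top is None else (GAP_LEN if col.top == "GAP" else weak_len)
        bottom = 0 if col.bottom is None else (GAP_LEN if col.bottom == "GAP" else weak_len)
        out.append((top, bottom))
    return out


def encode_image(rna: StructuredRNA) -> tuple[np.ndarray, np.ndarray]:
    """Encode to the (100, 25, 5) one-hot image and length-100 bond vector."""
    columns = align_arms(rna)
    lengths = bar_lengths(columns)
    img = np.zeros((N_COLS, N_ROWS, N_CHANNELS), dtype=np.uint8)
    m = np.zeros(N_COLS, dtype=np.uint8)
    for i, (col, (lt, lb)) in enumerate(zip(columns, lengths)):
        if col.top is not None:
            img[i, :lt, _COLOR_INDEX[col.top]] = 1
        if col.bottom is not None:
            img[i, N_ROWS - lb:, _COLOR_INDEX[col.bottom]] = 1
        if col.bond == "strong":
            m[i] = 1
    return img, m


def _read_bar(colpix: np.ndarray, col: int, side: str) -> tuple[str, int] | None:
    """Extract (color, length) of the bar attached to one edge of a column.

    ``colpix`` is the (25, 5) pixel block. Returns None if no bar; raises
    on malformed pixels (multi-hot, color changes inside a bar).
    """
    occupied = colpix.sum(axis=1)
    if (occupied > 1).any():
        rows = np.nonzero(occupied > 1)[0].tolist()
        raise ValueError(f"multi-hot pixels at column {col}, rows {rows}")
    order = range(N_ROWS) if side == "top" else range(N_ROWS - 1, -1, -1)
    rows = []
    for r in order:
        if occupied[r]:
            rows.append(r)
        else:
            break
    if not rows:
        return None
    channels = {int(np.argmax(colpix[r])) for r in rows}
    if len(channels) > 1:
        raise ValueError(f"bar with mixed colors at column {col} ({side})")
    return COLORS[channels.pop()], len(rows)


def bars_from_image(img: np.ndarray) -> list[BarSpec]:
    """All bars in column order, top before bottom within a column."""
    if img.shape != (N_COLS, N_ROWS, N_CHANNELS):
        raise ValueError(f"expected image shape {(N_COLS, N_ROWS, N_CHANNELS)}, "
                         f"got {img.shape}")
    bars: list[BarSpec] = []
    for i in range(N_COLS):
        top = _read_bar(img[i], i, "top")
        bottom = _read_bar(img[i], i, "bottom")
        if top is not None:
            bars.append(BarSpec(i, "top", top[0], top[1]))
        if bottom is not None:
            bars.append(BarSpec(i, "bottom", bottom[0], bottom[1]))
        # stray pixels between the two bars are malformed
        lt = top[1] if top else 0
        lb = bottom[1] if bottom else 0
        middle = img[i, lt:N_ROWS - lb, :]
        if middle.any():
            rows = (np.nonzero(middle.sum(axis=1))[0] + lt).tolist()
            raise ValueError(f"floating pixels at column {i}, rows {rows}")
    return bars


def decode_image(img: np.ndarray) -> StructuredRNA:
    """Inverse of :func:`encode_image` on its range.

    Reads the top row left to right, then the bottom row right to left;
    columns holding two nucleotide bars are base pairs, single nucleotide
    bars are loop nucleotides, a nucleotide facing a GAP is an unpaired
    stem position.
    """
    bars = bars_from_image(img)
    top: dict[int, BarSpec] = {b.column: b for b in bars if b.row_side == "top"}
    bottom: dict[int, BarSpec] = {b.column: b for b in bars if b.row_side == "bottom"}
    occupied = sorted(set(top) | set(bottom))
    if occupied and occupied != list(range(occupied[-1] + 1)):
        raise ValueError("occupied columns are not left-aligned and contiguous")

    top_seq: list[tuple[str, str]] = []     # (nucleotide, bracket)
    bottom_seq: list[tuple[str, str]] = []
    for i in occupied:
        t, b = top.get(i), bottom.get(i)
        t_color = t.color if t else None
        b_color = b.color if b else None
        if t_color == "GAP" and b_color == "GAP":
            raise ValueError(f"column {i}: two GAP bars")
        paired = (t_color not in (None, "GAP")) and (b_color not in (None, "GAP"))
        if t_color not in (None, "GAP"):
            top_seq.append((t_color, "(" if paired else "."))
        if b_color not in (None, "GAP"):
            bottom_seq.append((b_color, ")" if paired else "."))

    ordered = top_seq + bottom_seq[::-1]
    sequence = "".join(nt for nt, _ in ordered)
    structure = "".join(br for _, br in ordered)
    return StructuredRNA("decoded", sequence, structure)


def image_bond_vector(img: np.ndarray) -> np.ndarray:
    """Bond vector recomputed from pixels alone: a column is a strong bond
    iff both edges carry a 3-px nucleotide bar. Tolerant of generated
    images (no validation of bar grammar beyond edge runs)."""
    occ = img.sum(axis=2) > 0.5
    m = np.zeros(N_COLS, dtype=np.uint8)
    for i in range(N_COLS):
        t = 0
        while t < N_ROWS and occ[i, t]:
            t += 1
        b = 0
        while b < N_ROWS - t and occ[i, N_ROWS - 1 - b]:
            b += 1
        if t == STRONG_LEN and b == STRONG_LEN:
            t_col = int(np.argmax(img[i, 0]))
            b_col = int(np.argmax(img[i, N_ROWS - 1]))
            if COLORS[t_col] != "GAP" and COLORS[b_col] != "GAP":
                m[i] = 1
    return m


# display colors: A blue, C yellow, G green, U red, GAP black
_RGB = np.array([
    [40, 90, 220],     # A
    [235, 200, 40],    # C
    [60, 170, 60],     # G
    [210, 50, 50],     # U
    [0, 0, 0],         # GAP
], dtype=np.uint8)


def image_to_png(img: np.ndarray, path, upscale: int = 4) -> None:
    """Write a human-viewable PNG preview of a bar image (white background)."""
    from PIL import Image

    rgb = np.full((N_ROWS, N_COLS, 3), 255, dtype=np.uint8)
    occupied = img.sum(axis=2) > 0.5
    channel = img.argmax(axis=2)
    for col in range(N_COLS):
        for row in range(N_ROWS):
            if occupied[col, row]:
                rgb[row, col] = _RGB[channel[col, row]]
    Image.fromarray(rgb).resize((N_COLS * upscale, N_ROWS * upscale),
                                Image.NEAREST).save(path)
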