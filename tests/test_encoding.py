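"""Image/bond codec: alignment, bond classes, bar lengths, invertibility."""

import numpy as np
import pytest

from mirdescribe.encoding import (
    GAP_LEN,
    MAX_BAR,
    N_CHANNELS,
    N_COLS,
    N_ROWS,
    STRONG_LEN,
    align_arms,
    bar_lengths,
    bars_from_image,
    classify_bond,
    decode_image,
    encode_image,
    image_bond_vector,
)
from mirdescribe.records import StructuredRNA
from mirdescribe.simulate import GeneratorConfig, generate_dataset


@pytest.mark.parametrize("top,bottom,expected", [
    ("G", "C", "strong"), ("C", "G", "strong"), ("A", "U", "strong"),
    ("U", "A", "strong"),
    ("G", "U", "weak"), ("U", "G", "weak"), ("A", "G", "weak"),
    ("A", "GAP", "none"), ("GAP", "C", "none"), (None, "A", "none"),
])
def test_classify_bond(top, bottom, expected):
    assert classify_bond(top, bottom) == expected


def test_align_toy_stem():
    rec = StructuredRNA("t", "GGGAAACCC", "(((...)))")
    cols = align_arms(rec)
    # 3 paired columns followed by 3 single-bar loop columns
    assert len(cols) == 6
    for c in cols[:3]:
        assert (c.top, c.bottom, c.bond) == ("G", "C", "strong")
    assert [c.bond for c in cols[3:]] == ["none"] * 3
    # loop split: 2 on top, 1 on bottom
    assert cols[3].top == "A" and cols[3].bottom is None
    assert cols[4].top == "A" and cols[4].bottom is None
    assert cols[5].top is None and cols[5].bottom == "A"


def test_align_bulge_gets_gap():
    rec = StructuredRNA("t", "GGAGGAAACCCC", "((.((...))))")
    cols = align_arms(rec)
    bulge = cols[2]
    assert bulge.top == "A" and bulge.bottom == "GAP" and bulge.bond == "none"


def test_align_unpaired_input_all_gaps():
    rec = StructuredRNA("t", "ACGUA", ".....")
    cols = align_arms(rec)
    assert len(cols) == 5
    assert all(c.bottom == "GAP" and c.bond == "none" for c in cols)


def test_align_rejects_branched():
    rec = StructuredRNA("t", "GGAAACCGGAAACC", "((...))((...))")
    with pytest.raises(ValueError, match="stem-loop"):
        align_arms(rec)


def test_over_length_rejected():
    seq = "G" * 60 + "A" * 45 + "C" * 60
    struct = "(" * 60 + "." * 45 + ")" * 60
    with pytest.raises(ValueError, match="columns"):
        align_arms(StructuredRNA("t", seq, struct))


def test_bar_length_rule():
    """Strong bars are 3 px; weak/none runs grow 4,5,6,... capped at 12;
    gaps are always 2 px."""
    rec = StructuredRNA("t", "GGGAAACCC", "(((...)))")
    cols = align_arms(rec)
    lengths = bar_lengths(cols)
    assert lengths[:3] == [(3, 3)] * 3
    assert lengths[3] == (4, 0)
    assert lengths[4] == (5, 0)
    assert lengths[5] == (0, 6)

    # a long unpaired run saturates at the 12-px cap
    rec2 = StructuredRNA("t2", "A" * 15, "." * 15)
    lens2 = bar_lengths(align_arms(rec2))
    tops = [t for t, _ in lens2]
    assert tops == [min(4 + i, MAX_BAR) for i in range(15)]
    assert all(b == GAP_LEN for _, b in lens2)

    # weak run resets after a strong column
    rec3 = StructuredRNA("t3", "GGUAAACAACC", "(((....))).")
    lens3 = bar_lengths(align_arms(rec3))
    assert lens3[1] == (STRONG_LEN, STRONG_LEN)


def test_encode_shape_and_bond_vector():
    recs = generate_dataset(GeneratorConfig(n_samples=20, seed=3))
    for rec in recs:
        img, m = encode_image(rec)
        assert img.shape == (N_COLS, N_ROWS, N_CHANNELS)
        assert m.shape == (N_COLS,)
        # bond vector equals an independent per-column recomputation
        cols = align_arms(rec)
        expected = np.zeros(N_COLS, dtype=np.uint8)
        for i, c in enumerate(cols):
            expected[i] = 1 if classify_bond(c.top, c.bottom) == "strong" else 0
        assert np.array_equal(m, expected)
        # one-hot everywhere, row 12 always background
        assert img.sum(axis=2).max() <= 1
        assert img[:, 12, :].sum() == 0


def test_fully_paired_stem_gives_prefix_of_ones():
    rec = StructuredRNA("t", "GGGGGAAAACCCCC", "(((((....)))))")
    _, m = encode_image(rec)
    assert np.array_equal(m[:5], np.ones(5, dtype=np.uint8))
    assert m[5:].sum() == 0


def test_round_trip_identity(small_dataset):
    for rec in small_dataset:
        img, _ = encode_image(rec)
        dec = decode_image(img)
        assert dec.sequence == rec.sequence
        assert dec.structure == rec.structure


def test_decode_empty_image():
    img = np.zeros((N_COLS, N_ROWS, N_CHANNELS), dtype=np.uint8)
    dec = decode_image(img)
    assert dec.sequence == "" and dec.structure == ""


def test_decode_single_bulge_column():
    # hand-built column: 2-px GAP bar on top, 4-px A bar on bottom
    img = np.zeros((N_COLS, N_ROWS, N_CHANNELS), dtype=np.uint8)
    img[0, :2, 4] = 1            # GAP channel, top
    img[0, N_ROWS - 4:, 0] = 1   # A channel, bottom
    dec = decode_image(img)
    assert dec.sequence == "A" and dec.structure == "."


def test_decode_rejects_multi_hot_pixels():
    img = np.zeros((N_COLS, N_ROWS, N_CHANNELS), dtype=np.uint8)
    img[0, 0, 0] = 1
    img[0, 0, 1] = 1
    with pytest.raises(ValueError, match="multi-hot"):
        decode_image(img)


def test_decode_rejects_floating_pixels():
    img = np.zeros((N_COLS, N_ROWS, N_CHANNELS), dtype=np.uint8)
    img[0, 5, 0] = 1  # pixel attached to neither edge
    with pytest.raises(ValueError, match="floating"):
        decode_image(img)


def test_bars_respect_budget(small_dataset):
    for rec in small_dataset[:100]:
        img, _ = encode_image(rec)
        bars = bars_from_image(img)
        assert max(b.length for b in bars) <= MAX_BAR
        assert max(b.column for b in bars) < N_COLS
        gap_bars = [b for b in bars if b.color == "GAP"]
        assert all(b.length == GAP_LEN for b in gap_bars)


def test_image_bond_vector_matches_encoder(small_dataset):
    for rec in small_dataset[:50]:
        img, m = encode_image(rec)
        assert np.array_equal(image_bond_vector(img), m)
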