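"""Structural features of stem-loop RNA, computed from the dot-bracket alone.

These are the features the latent-space decision tree splits on: terminal
loop presence and size, stem length (paired columns), the Watson-Crick
fraction of the stem, total length, and bulge statistics including the
largest asymmetric bulge (|5'-side - 3'-side| unpaired run between
consecutive pairs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encoding import classify_bond
from .records import StructuredRNA, parse_pairs

__all__ = [
    "FEATURE_COLUMNS", "BINARY_FEATURES", "CONTINUOUS_FEATURES",
    "FEATURE_FAMILIES", "feature_family",
    "extract_features", "build_feature_table",
    "quantile_thresholds", "binarize_features",
]

FEATURE_COLUMNS = [
    "has_terminal_loop", "loop_length", "stem_length", "pair_fraction",
    "total_length", "n_bulges", "max_bulge_size", "max_asymmetric_bulge",
]
BINARY_FEATURES = ["has_terminal_loop"]
CONTINUOUS_FEATURES = [f for f in FEATURE_COLUMNS if f not in BINARY_FEATURES]

# structural families used when comparing a learned description against a
# planted rule (several features measure the same structural aspect)
FEATURE_FAMILIES = {
    "pair_fraction": "pairing",
    "stem_length": "length",
    "total_length": "length",
    "loop_length": "loop",
    "has_terminal_loop": "loop",
    "n_bulges": "bulge",
    "max_bulge_size": "bulge",
    "max_asymmetric_bulge": "bulge",
}

MIN_LOOP = 3  # minimal unpaired run to count as a terminal loop


def feature_family(column_name: str) -> str:
    """Family of a (possibly binarized) feature column name."""
    base = column_name.split(">", 1)[0].split("<", 1)[0]
    return FEATURE_FAMILIES[base]


def extract_features(rna: StructuredRNA) -> dict[str, float]:
    """One feature row; empty/unpairable structures give an all-zero row
    (except total_length, which is always the sequence length)."""
    n = len(rna)
    pairs = parse_pairs(rna.structure)
    row = {f: 0 for f in FEATURE_COLUMNS}
    row["total_length"] = n
    if not pairs:
        return row

    strong = sum(
        1 for i, j in pairs
        if classify_bond(rna.sequence[i], rna.sequence[j]) == "strong"
    )
    row["stem_length"] = len(pairs)
    row["pair_fraction"] = strong / len(pairs)

    i_inner, j_inner = pairs[-1]
    loop_len = j_inner - i_inner - 1
    row["loop_length"] = loop_len
    row["has_terminal_loop"] = int(loop_len >= MIN_LOOP)

    # unpaired runs between consecutive pairs, plus dangling ends
    gaps: list[tuple[int, int]] = []
    first_i, first_j = pairs[0]
    if first_i > 0 or first_j < n - 1:
        gaps.append((first_i, n - 1 - first_j))
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        a, b = i2 - i1 - 1, j1 - j2 - 1
        if a or b:
            gaps.append((a, b))
    row["n_bulges"] = len(gaps)
    row["max_bulge_size"] = max((max(a, b) for a, b in gaps), default=0)
    row["max_asymmetric_bulge"] = max((abs(a - b) for a, b in gaps), default=0)
    return row


def build_feature_table(records: list[StructuredRNA]) -> pd.DataFrame:
    """Feature table indexed by record id, columns in canonical order."""
    table = pd.DataFrame([extract_features(r) for r in records],
                         index=[r.id for r in records])
    return table[FEATURE_COLUMNS].astype(float)


def quantile_thresholds(table: pd.DataFrame,
                        quantiles=(0.2, 0.4, 0.6, 0.8)) -> dict[str, list[float]]:
    """Default per-feature thresholds: empirical quintiles (deduplicated)."""
    thresholds: dict[str, list[float]] = {}
    for feat in CONTINUOUS_FEATURES:
        if feat not in table.columns:
            continue
        qs = np.quantile(table[feat].to_numpy(), quantiles)
        uniq = sorted(set(round(float(q), 6) for q in qs))
        # drop degenerate thresholds at the feature's extremes
        lo, hi = table[feat].min(), table[feat].max()
        uniq = [q for q in uniq if lo < q < hi]
        if uniq:
            thresholds[feat] = uniq
    return thresholds


def binarize_features(table: pd.DataFrame,
                      thresholds: dict[str, list[float]] | None = None
                      ) -> pd.DataFrame:
    """Binary feature matrix with machine-parseable column names.

    One column ``"<feature>><threshold>"`` per (feature, threshold) pair,
    plus pass-through of already-binary features. Threshold lists must be
    strictly increasing and non-empty.
    """
    if thresholds is None:
        thresholds = quantile_thresholds(table)
    out: dict[str, np.ndarray] = {}
    for feat in table.columns:
        if feat in BINARY_FEATURES:
            out[feat] = table[feat].to_numpy().astype(int)
            continue
        ths = thresholds.get(feat)
        if ths is None:
            continue
        if len(ths) == 0:
            raise ValueError(f"empty threshold list for continuous feature {feat!r}")
        if any(b <= a for a, b in zip(ths, ths[1:])):
            raise ValueError(f"thresholds for {feat!r} must be strictly increasing")
        for t in ths:
            out[f"{feat}>{t:g}"] = (table[feat].to_numpy() > t).astype(int)
    return pd.DataFrame(out, index=table.index)
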