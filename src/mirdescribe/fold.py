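"""Single stem-loop folding by dynamic programming.

This is a deliberately simple maximum-pairing folder, not a thermodynamic
one: it finds the dot-bracket structure with the largest number of
complementary pairs (Watson-Crick plus G-U wobble) under the constraints
that pairing is strictly nested, non-branching (one hairpin) and the
terminal loop spans at least ``min_loop`` nucleotides. It provides the
refold fallback used when building shuffled decoy sequences, whose
"suboptimally folded" structures the downstream image encoding can always
represent (the 2-row bar image cannot draw multibranched structures).
"""

from __future__ import annotations

import numpy as np

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

__all__ = ["hairpin_fold"]


def hairpin_fold(sequence: str, min_loop: int = 3) -> str:
    """Best single stem-loop structure for `sequence` in dot-bracket form.

    Recurrence over intervals [i, j]:
      H(i,j) = max( H(i+1,j-1) + pairable(i,j), H(i+1,j), H(i,j-1) )
    with H(i,j) = 0 whenever j - i <= min_loop. Ties prefer pairing, then
    skipping on the 5' side, which makes the traceback deterministic.
    """
    n = len(sequence)
    if n == 0:
        return ""
    H = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = max(H[i + 1, j], H[i, j - 1])
            if (sequence[i], sequence[j]) in _CAN_PAIR:
                best = max(best, H[i + 1, j - 1] + 1)
            H[i, j] = best

    structure = ["."] * n
    i, j = 0, n - 1
    while j - i > min_loop:
        pairable = (sequence[i], sequence[j]) in _CAN_PAIR
        if pairable and H[i, j] == H[i + 1, j - 1] + 1:
            structure[i], structure[j] = "(", ")"
            i, j = i + 1, j - 1
        elif H[i, j] == H[i + 1, j]:
            i += 1
        else:
            j -= 1
    return "".join(structure)
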