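"""Synthetic hairpin / decoy generator.

Emulates the construction of a balanced precursor-miRNA image dataset
without any external download: positives are single stem-loop molecules
with a mostly Watson-Crick stem, a terminal loop and occasional one-sided
bulges; negatives are (a) dinucleotide-shuffled positives refolded with the
DP fallback folder, (b) hairpins whose stem is forced to a low
Watson-Crick fraction (wobble-dominated), or (c) truncated short hairpins.
Every realized structural parameter is recorded in the record metadata so
that downstream feature extraction can be tested against planted values.

A separate entry point, :func:`generate_planted_rule_dataset`, builds the
dataset for the planted-description experiment, where the class label is a
known conjunction of structural conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold import hairpin_fold
from .records import StructuredRNA

__all__ = [
    "GeneratorConfig",
    "PlantedRuleConfig",
    "generate_hairpin",
    "generate_negative",
    "generate_dataset",
    "generate_planted_rule_dataset",
    "dinucleotide_shuffle",
]

_WC = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
_WOBBLE = [("G", "U"), ("U", "G")]

MAX_COLUMNS = 100


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Stem lengths count base-paired columns; loop length counts unpaired
    terminal-loop nucleotides; ``pair_fraction_range`` bounds the fraction of
    stem pairs that are Watson-Crick (strong); ``bulge_rate`` is the
    per-stem-gap probability of inserting a one-sided bulge.
    """

    n_samples: int = 1000
    stem_length_range: tuple[int, int] = (15, 35)
    loop_length_range: tuple[int, int] = (3, 12)
    pair_fraction_range: tuple[float, float] = (0.75, 1.0)
    bulge_rate: float = 0.10
    max_bulge_size: int = 4
    class_balance: float = 0.5
    seed: int = 0
    negative_pair_ceiling: float = 0.30
    negative_mechanisms: tuple[str, ...] = ("shuffle", "low_pairing", "short")

    def __post_init__(self):
        lo, hi = self.stem_length_range
        llo, lhi = self.loop_length_range
        plo, phi = self.pair_fraction_range
        if not (1 <= lo <= hi):
            raise ValueError("stem_length_range must be a non-empty positive interval")
        if not (3 <= llo <= lhi):
            raise ValueError("loop_length_range must be >= 3 (minimal hairpin loop)")
        if not (0.0 <= plo <= phi <= 1.0):
            raise ValueError("pair_fraction_range must be within [0, 1]")
        if not 0.0 <= self.bulge_rate <= 1.0:
            raise ValueError("bulge_rate must be in [0, 1]")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must be in [0, 1]")
        if self.max_bulge_size < 1:
            raise ValueError("max_bulge_size must be >= 1")
        if not 0.0 < self.negative_pair_ceiling <= 1.0:
            raise ValueError("negative_pair_ceiling must be in (0, 1]")
        unknown = set(self.negative_mechanisms) - {"shuffle", "low_pairing", "short"}
        if unknown:
            raise ValueError(f"unknown negative mechanisms {sorted(unknown)}")
        if hi + lhi > MAX_COLUMNS:
            raise ValueError(
                f"stem + loop ({hi} + {lhi}) exceeds the {MAX_COLUMNS}-column image"
            )


def _random_nt(rng: np.random.Generator, k: int = 1) -> list[str]:
    return list(rng.choice(list("ACGU"), size=k))


def _build_hairpin(stem: int, loop: int, n_strong: int, bulges: list[tuple[int, int, str]],
                   rng: np.random.Generator) -> tuple[str, str]:
    """Assemble sequence and dot-bracket from planted parameters.

    `bulges` is a list of (gap_index, size, side) with gap_index in
    [0, stem-2] counting the gap after that pair (outermost pair first).
    """
    strong_at = set(rng.choice(stem, size=n_strong, replace=False)) if n_strong else set()
    bulge_at = {g: (size, side) for g, size, side in bulges}

    seq5, str5, seq3, str3 = [], [], [], []   # 3' arm collected inner->outer
    for k in range(stem):
        top, bottom = (
            _WC[rng.integers(len(_WC))] if k in strong_at
            else _WOBBLE[rng.integers(len(_WOBBLE))]
        )
        seq5.append(top)
        str5.append("(")
        seq3.append(bottom)
        str3.append(")")
        if k in bulge_at:
            size, side = bulge_at[k]
            nts = _random_nt(rng, size)
            if side == "5p":
                seq5.extend(nts)
                str5.extend("." * size)
            else:
                seq3.extend(nts)
                str3.extend("." * size)
    loop_nts = _random_nt(rng, loop)
    sequence = "".join(seq5) + "".join(loop_nts) + "".join(reversed(seq3))
    structure = "".join(str5) + "." * loop + "".join(reversed(str3))
    return sequence, structure


def generate_hairpin(config: GeneratorConfig, rng: np.random.Generator,
                     rec_id: str = "hairpin", label: int = 1) -> StructuredRNA:
    """Draw one positive single stem-loop record.

    Realized stem length, loop length, Watson-Crick pair fraction and bulge
    statistics are stored in ``meta`` for planted-rule tests. Raises
    ``ValueError`` when the aligned structure cannot fit the 100-column
    image.
    """
    stem = int(rng.integers(config.stem_length_range[0], config.stem_length_range[1] + 1))
    loop = int(rng.integers(config.loop_length_range[0], config.loop_length_range[1] + 1))
    p = float(rng.uniform(*config.pair_fraction_range))
    n_strong = int(round(p * stem))

    if stem + loop > MAX_COLUMNS:
        raise ValueError(
            f"stem {stem} + loop {loop} exceeds {MAX_COLUMNS} encoded positions"
        )
    budget = MAX_COLUMNS - stem - loop
    bulges: list[tuple[int, int, str]] = []
    for g in range(stem - 1):
        if rng.uniform() < config.bulge_rate:
            size = int(rng.integers(1, config.max_bulge_size + 1))
            if size > budget:
                continue
            side = "5p" if rng.uniform() < 0.5 else "3p"
            bulges.append((g, size, side))
            budget -= size

    sequence, structure = _build_hairpin(stem, loop, n_strong, bulges, rng)
    sizes = [s for _, s, _ in bulges]
    meta = {
        "kind": "hairpin",
        "stem_length": stem,
        "loop_length": loop,
        "pair_fraction": round(n_strong / stem, 6),
        "n_bulges": len(bulges),
        "max_bulge_size": max(sizes) if sizes else 0,
        "max_asymmetric_bulge": max(sizes) if sizes else 0,
        "total_length": len(sequence),
    }
    return StructuredRNA(rec_id, sequence, structure, label=label, meta=meta)


# -------------------------------------------------------------------- decoys

def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson dinucleotide shuffle (preserves dinucleotide counts)."""
    n = len(sequence)
    if n < 4 or len(set(sequence)) < 2:
        chars = list(sequence)
        rng.shuffle(chars)
        return "".join(chars)

    out_edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        out_edges.setdefault(a, []).append(b)
    first, last = sequence[0], sequence[-1]
    vertices = sorted(out_edges)

    for _ in range(200):
        # pick a candidate "last edge" for every vertex except the terminal one
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = out_edges[v][int(rng.integers(len(out_edges[v])))]
        # the chosen edges must connect every vertex to the terminal vertex
        ok = True
        for v in last_edge:
            seen, cur = {v}, v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - extremely unlikely for 4-letter RNA
        chars = list(sequence)
        rng.shuffle(chars)
        return "".join(chars)

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(out_edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        shuffled[v] = rest

    walk = [first]
    ptr = {v: 0 for v in vertices}
    for _ in range(n - 1):
        v = walk[-1]
        walk.append(shuffled[v][ptr[v]])
        ptr[v] += 1
    return "".join(walk)


def generate_negative(config: GeneratorConfig, rng: np.random.Generator,
                      rec_id: str = "decoy") -> StructuredRNA:
    """Draw one negative record by one of three documented mechanisms.

    (a) ``shuffle``: dinucleotide shuffle of a freshly drawn positive,
        refolded with the DP fallback folder;
    (b) ``low_pairing``: hairpin whose Watson-Crick fraction is forced
        below ``negative_pair_ceiling``;
    (c) ``short``: truncated hairpin far below plausible pre-miRNA length.
    """
    mech = config.negative_mechanisms[int(rng.integers(len(config.negative_mechanisms)))]
    if mech == "shuffle":
        for _ in range(20):
            pos = generate_hairpin(config, rng)
            seq = dinucleotide_shuffle(pos.sequence, rng)
            structure = hairpin_fold(seq)
            # aligned width is n - n_pairs; skip rare draws that overflow
            if len(seq) - structure.count("(") <= MAX_COLUMNS:
                break
        return StructuredRNA(rec_id, seq, structure, label=0,
                             meta={"kind": "neg_shuffle"})
    if mech == "low_pairing":
        stem = int(rng.integers(config.stem_length_range[0],
                                config.stem_length_range[1] + 1))
        loop = int(rng.integers(config.loop_length_range[0],
                                config.loop_length_range[1] + 1))
        p = float(rng.uniform(0.0, config.negative_pair_ceiling))
        n_strong = int(np.floor(p * stem))  # floor keeps fraction <= ceiling
        sequence, structure = _build_hairpin(stem, loop, n_strong, [], rng)
        meta = {"kind": "neg_low_pairing", "stem_length": stem, "loop_length": loop,
                "pair_fraction": round(n_strong / stem, 6), "n_bulges": 0,
                "max_bulge_size": 0, "max_asymmetric_bulge": 0,
                "total_length": len(sequence)}
        return StructuredRNA(rec_id, sequence, structure, label=0, meta=meta)
    # short truncated hairpin
    stem = int(rng.integers(3, 9))
    loop = int(rng.integers(3, 7))
    p = float(rng.uniform(*config.pair_fraction_range))
    n_strong = int(round(p * stem))
    sequence, structure = _build_hairpin(stem, loop, n_strong, [], rng)
    meta = {"kind": "neg_short", "stem_length": stem, "loop_length": loop,
            "pair_fraction": round(n_strong / stem, 6), "n_bulges": 0,
            "max_bulge_size": 0, "max_asymmetric_bulge": 0,
            "total_length": len(sequence)}
    return StructuredRNA(rec_id, sequence, structure, label=0, meta=meta)


def generate_dataset(config: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> list[StructuredRNA]:
    """Balanced labeled dataset; byte-identical under a fixed config/seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_pos = int(round(config.n_samples * config.class_balance))
    records = [generate_hairpin(config, rng, rec_id=f"pos{i:05d}")
               for i in range(n_pos)]
    records += [generate_negative(config, rng, rec_id=f"neg{i:05d}")
                for i in range(config.n_samples - n_pos)]
    order = rng.permutation(len(records))
    return [records[i] for i in order]


# ------------------------------------------------------------- planted rules

@dataclass(frozen=True)
class PlantedRuleConfig:
    """Dataset for the planted-description experiment.

    The class label is the conjunction
    ``pair_fraction > pair_threshold AND total_length > length_threshold
    AND max_asymmetric_bulge < bulge_threshold``. Each condition is
    satisfied independently with the given probability, and values are
    drawn away from the thresholds (small margins) so the planted rule is
    identifiable at the resolution of quantile binarization.
    """

    n_samples: int = 2000
    seed: int = 0
    pair_threshold: float = 0.7
    length_threshold: int = 60
    bulge_threshold: int = 5
    p_satisfy: tuple[float, float, float] = (0.8, 0.8, 0.6)
    loop_length_range: tuple[int, int] = (3, 12)


def _planted_record(cfg: PlantedRuleConfig, rng: np.random.Generator,
                    rec_id: str) -> StructuredRNA:
    sat_pair = rng.uniform() < cfg.p_satisfy[0]
    sat_len = rng.uniform() < cfg.p_satisfy[1]
    sat_bulge = rng.uniform() < cfg.p_satisfy[2]

    pair = float(rng.uniform(cfg.pair_threshold + 0.02, 1.0)) if sat_pair else \
        float(rng.uniform(0.30, cfg.pair_threshold - 0.04))
    loop = int(rng.integers(cfg.loop_length_range[0], cfg.loop_length_range[1] + 1))

    if sat_bulge:
        n_bulges = int(rng.integers(0, 3))
        sizes = [int(rng.integers(1, cfg.bulge_threshold)) for _ in range(n_bulges)]
    else:
        n_bulges = int(rng.integers(1, 3))
        sizes = [int(rng.integers(cfg.bulge_threshold + 1, cfg.bulge_threshold + 4))]
        sizes += [int(rng.integers(1, cfg.bulge_threshold))
                  for _ in range(n_bulges - 1)]
    bulge_total = sum(sizes)

    target_len = (float(rng.uniform(cfg.length_threshold + 2, 96))
                  if sat_len else
                  float(rng.uniform(24, cfg.length_threshold - 2)))
    stem = max(4, int(round((target_len - loop - bulge_total) / 2)))
    total = 2 * stem + loop + bulge_total
    # nudge the stem so the realized total stays on the intended side
    if sat_len and total < cfg.length_threshold + 2:
        stem += (cfg.length_threshold + 2 - total + 1) // 2
    elif not sat_len and total > cfg.length_threshold - 2:
        stem = max(4, stem - (total - (cfg.length_threshold - 2) + 1) // 2)
    total = 2 * stem + loop + bulge_total

    n_strong = int(round(pair * stem))
    # rounding must not cross the planted threshold
    if sat_pair and n_strong / stem <= cfg.pair_threshold:
        n_strong = min(stem, n_strong + 1)
    elif not sat_pair and n_strong / stem > cfg.pair_threshold:
        n_strong -= 1

    gaps = list(rng.choice(max(stem - 1, 1), size=min(len(sizes), stem - 1),
                           replace=False)) if sizes else []
    bulges = [(int(g), s, "5p" if rng.uniform() < 0.5 else "3p")
              for g, s in zip(gaps, sizes)]
    sizes = [s for _, s, _ in bulges]

    sequence, structure = _build_hairpin(stem, loop, n_strong, bulges, rng)
    label = int(sat_pair and sat_len and (max(sizes) if sizes else 0) < cfg.bulge_threshold)
    meta = {
        "kind": "planted",
        "stem_length": stem,
        "loop_length": loop,
        "pair_fraction": round(n_strong / stem, 6),
        "n_bulges": len(bulges),
        "max_bulge_size": max(sizes) if sizes else 0,
        "max_asymmetric_bulge": max(sizes) if sizes else 0,
        "total_length": len(sequence),
    }
    return StructuredRNA(rec_id, sequence, structure, label=label, meta=meta)


def generate_planted_rule_dataset(cfg: PlantedRuleConfig) -> list[StructuredRNA]:
    rng = np.random.default_rng(cfg.seed)
    return [_planted_record(cfg, rng, f"planted{i:05d}") for i in range(cfg.n_samples)]
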