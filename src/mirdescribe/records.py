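"""Canonical input record: an RNA sequence with its secondary structure.

A :class:`StructuredRNA` couples a sequence over ``{A,C,G,U}`` with a
Vienna-style dot-bracket string of the same length (matched parentheses are
base pairs, dots are unpaired). Datasets are stored as plain-text files:
a FASTA file for sequences, a ``.dbn`` dot-bracket sidecar, and a TSV label
file — all round-trippable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGU"

__all__ = ["StructuredRNA", "parse_pairs", "is_single_stem_loop",
           "write_dataset", "read_dataset"]


def parse_pairs(structure: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, from a dot-bracket string.

    Raises ``ValueError`` on unbalanced brackets or characters outside
    ``(.)``. Nested-only pairing is implied by the bracket grammar
    (pseudoknots would need additional bracket types, which are rejected).
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def is_single_stem_loop(structure: str) -> bool:
    """True when all pairs form one non-branching, strictly nested stem."""
    pairs = parse_pairs(structure)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j2 < j1):
            return False
    return True


@dataclass
class StructuredRNA:
    id: str
    sequence: str
    structure: str
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        bad = set(self.sequence) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"{self.id}: invalid nucleotides {sorted(bad)}")
        parse_pairs(self.structure)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return parse_pairs(self.structure)

    def __len__(self) -> int:
        return len(self.sequence)


# ------------------------------------------------------------------------ I/O

def _meta_to_str(meta: dict) -> str:
    return " ".join(f"{k}={v!r}" if isinstance(v, str) else f"{k}={v}"
                    for k, v in meta.items())


def _parse_meta(text: str) -> dict:
    meta: dict = {}
    for tok in text.split():
        if "=" not in tok:
            continue
        k, v = tok.split("=", 1)
        if v.startswith("'") and v.endswith("'"):
            meta[k] = v[1:-1]
            continue
        try:
            meta[k] = int(v)
        except ValueError:
            try:
                meta[k] = float(v)
            except ValueError:
                meta[k] = v
    return meta


def write_dataset(records: list[StructuredRNA], path: str | Path) -> None:
    """Write FASTA + dot-bracket sidecar + TSV labels under ``path``."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        seqs = [SeqRecord(Seq(r.sequence), id=r.id, description=_meta_to_str(r.meta))
                for r in records]
        SeqIO.write(seqs, path / "sequences.fasta", "fasta")
        with open(path / "structures.dbn", "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.sequence}\n{r.structure}\n")
        with open(path / "labels.tsv", "w") as fh:
            fh.write("id\tlabel\n")
            for r in records:
                fh.write(f"{r.id}\t{'' if r.label is None else r.label}\n")
    except OSError as exc:
        raise OSError(f"failed writing dataset to {path}: {exc}") from exc


def read_dataset(path: str | Path) -> list[StructuredRNA]:
    path = Path(path)
    try:
        seqs = {rec.id: rec for rec in SeqIO.parse(path / "sequences.fasta", "fasta")}
        structures: dict[str, str] = {}
        order: list[str] = []
        with open(path / "structures.dbn") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        for i in range(0, len(lines), 3):
            rid = lines[i][1:].split()[0]
            structures[rid] = lines[i + 2]
            order.append(rid)
        labels: dict[str, int | None] = {}
        with open(path / "labels.tsv") as fh:
            next(fh)
            for ln in fh:
                rid, _, lab = ln.rstrip("\n").partition("\t")
                labels[rid] = int(lab) if lab else None
    except OSError as exc:
        raise OSError(f"failed reading dataset from {path}: {exc}") from exc

    records = []
    for rid in order:
        rec = seqs[rid]
        desc = rec.description
        if desc.startswith(rid):
            desc = desc[len(rid):].strip()
        records.append(StructuredRNA(
            id=rid, sequence=str(rec.seq), structure=structures[rid],
            label=labels.get(rid), meta=_parse_meta(desc)))
    return records
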