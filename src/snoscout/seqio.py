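"""Sequence records, FASTA I/O and shuffling utilities.

All sequences are normalized to the RNA alphabet {A, C, G, U}. Coordinates
are 0-based half-open everywhere inside the package; conversion to 1-based
inclusive happens only when writing GFF3.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Tuple

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass
class SequenceRecord:
    """An identified, RNA-normalized nucleotide sequence.

    ``source_coordinates`` optionally records where the sequence came from as
    ``(contig, start, end, strand)`` with 0-based half-open coordinates.
    """

    id: str
    residues: str
    description: str = ""
    source_coordinates: Optional[Tuple[str, int, int, str]] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - set(RNA_ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-ACGU residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=self.residues.translate(COMPLEMENT)[::-1],
            description=self.description,
            source_coordinates=self.source_coordinates,
        )


def normalize_residues(raw: str) -> str:
    """Uppercase and map DNA T to RNA U. Does not validate the alphabet."""
    return raw.upper().replace("T", "U")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into RNA-normalized :class:`SequenceRecord` objects.

    Records containing characters outside {A, C, G, U, T} after
    normalization (including any N) are skipped with a logged warning.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file contains no FASTA entries at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    n_entries = 0
    n_skipped = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        residues = normalize_residues(str(entry.seq))
        if not residues or set(residues) - set(RNA_ALPHABET):
            n_skipped += 1
            logger.warning(
                "skipping record %r: residues outside {A,C,G,U,T}", entry.id
            )
            continue
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(SequenceRecord(id=entry.id, residues=residues, description=desc))
    if n_entries == 0:
        raise ValueError(f"no FASTA entries in {path}")
    if n_skipped:
        logger.warning("skipped %d of %d records in %s", n_skipped, n_entries, path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def composition(seq: str) -> Tuple[float, float, float]:
    """Return (AC, GU, GC) content fractions of ``seq``.

    AC + GU = 1 always; GC is the classic GC content.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("composition of empty sequence is undefined")
    a = seq.count("A")
    c = seq.count("C")
    g = seq.count("G")
    u = seq.count("U")
    return (a + c) / n, (g + u) / n, (g + c) / n


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of the residues (exact mononucleotide conservation)."""
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Shuffle ``seq`` preserving the exact multiset of overlapping dinucleotides.

    Uses the Altschul–Erickson construction: the dinucleotides form the edge
    multiset of a directed multigraph over the nucleotides; a shuffle is an
    Euler path from the first to the last residue. A uniformly random
    arborescence toward the final residue (sampled with Wilson's loop-erased
    random walk) fixes the last exit edge of every vertex, the remaining
    edges are permuted uniformly, and the Euler path is read off. The output
    therefore conserves length, mononucleotide counts, dinucleotide counts,
    and the first and last residue exactly.
    """
    if len(seq) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")
    rng = np.random.default_rng(seed)
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(set(edges) | {last})
    if len(vertices) == 1:
        return seq

    # Wilson's algorithm: arborescence rooted at the terminal residue.
    in_tree = {last}
    tree_edge: dict[str, str] = {}
    for v in vertices:
        if v in in_tree:
            continue
        nxt: dict[str, str] = {}
        u = v
        while u not in in_tree:
            succ = edges[u]
            nxt[u] = succ[int(rng.integers(len(succ)))]
            u = nxt[u]
        u = v
        while u not in in_tree:
            tree_edge[u] = nxt[u]
            in_tree.add(u)
            u = nxt[u]

    ordered: dict[str, list[str]] = {}
    for u, lst in edges.items():
        lst = list(lst)
        if u in tree_edge:
            lst.remove(tree_edge[u])
            rng.shuffle(lst)
            lst.append(tree_edge[u])
        else:
            rng.shuffle(lst)
        ordered[u] = lst

    out = [first]
    idx: dict[str, int] = defaultdict(int)
    u = first
    for _ in range(len(seq) - 1):
        v = ordered[u][idx[u]]
        idx[u] += 1
        out.append(v)
        u = v
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for a, b in zip(seq, seq[1:]):
        counts[a + b] += 1
    return dict(counts)
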