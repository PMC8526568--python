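"""Ortholog sets and species-concatenated alignments.

Each protein's orthologs arrive as a pre-aligned FASTA keyed by species
(``>SPECIES|accession`` headers).  Orthologs of the two proteins are
joined per species — only species present in both sets contribute a row —
giving the concatenated MSA (cMSA) on which inter-protein couplings are
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AA_ALPHABET",
    "OrthologSet",
    "ConcatenatedMSA",
    "concat_by_species",
    "read_ortholog_fasta",
    "write_ortholog_fasta",
    "encode_sequences",
]

#: gap first so it is the reference state excluded from coupling norms
AA_ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"
_AA_TO_CODE = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_STATES = len(AA_ALPHABET)  # 21


def encode_sequences(seqs: Iterable[str]) -> np.ndarray:
    """Integer-encode aligned sequences; unknown residues become gaps."""
    rows = []
    for s in seqs:
        rows.append([_AA_TO_CODE.get(ch, 0) for ch in s.upper()])
    return np.asarray(rows, dtype=np.int8)


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[c] for c in codes)


@dataclass
class OrthologSet:
    """Aligned orthologs of one protein, one sequence per species."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty ortholog set")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> set[str]:
        return set(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def reassigned(self, rng: np.random.Generator) -> "OrthologSet":
        """Sequences randomly reassigned to species (phylogeny-breaking shuffle)."""
        keys = sorted(self.sequences)
        vals = [self.sequences[k] for k in keys]
        perm = rng.permutation(len(keys))
        return OrthologSet({k: vals[p] for k, p in zip(keys, perm)})


@dataclass
class ConcatenatedMSA:
    """Two-protein alignment joined by species.

    ``matrix`` is (N, len_a + len_b) of integer state codes; ``boundary``
    is the first column of protein B.
    """

    species: list[str]
    matrix: np.ndarray
    boundary: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.species):
            raise ValueError("matrix must be (n_species, total_length)")
        if not (0 < self.boundary < self.matrix.shape[1]):
            raise ValueError("boundary must split the columns into two non-empty blocks")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def len_a(self) -> int:
        return self.boundary

    @property
    def len_b(self) -> int:
        return self.n_cols - self.boundary


def concat_by_species(set_a: OrthologSet, set_b: OrthologSet) -> ConcatenatedMSA:
    """Join two ortholog sets on their shared species (sorted for determinism)."""
    shared = sorted(set_a.species & set_b.species)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared species; need at least 2")
    rows = [set_a.sequences[sp] + set_b.sequences[sp] for sp in shared]
    return ConcatenatedMSA(
        species=shared,
        matrix=encode_sequences(rows),
        boundary=set_a.alignment_length,
    )


def read_ortholog_fasta(path: str | Path) -> OrthologSet:
    """Read an aligned FASTA with ``>SPECIES|accession`` (or bare) headers."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        species = rec.id.split("|")[0]
        if species in seqs:
            raise ValueError(f"duplicate species key {species!r} in {path}")
        seqs[species] = str(rec.seq)
    return OrthologSet(seqs)


def write_ortholog_fasta(oset: OrthologSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{sp}|synthetic", description="")
        for sp, seq in sorted(oset.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")
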