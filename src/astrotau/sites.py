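"""Peptide-to-isoform mapping and canonical phosphosite numbering for tau.

Human CNS tau exists as six splice isoforms (0N/1N/2N x 3R/4R).  The field
labels phosphosites on the coordinates of the longest isoform, 2N4R
(441 residues): T181, S202, S262 and so on.  Every shorter CNS isoform is
the 2N4R sequence with one or more contiguous exon-encoded blocks removed
(exon 2 = residues 45-73, exon 3 = 74-102, exon 10 = 275-305), so each
isoform position maps to a unique canonical position through an ungapped
block table.  This module builds that table, locates peptides inside the
isoforms, and translates peptide-local phospho offsets to canonical site
labels such as "S202".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .io import read_fasta

CANONICAL_ACCESSION = "P10636-8"
CANONICAL_LENGTH = 441

PHOSPHO_RESIDUES = frozenset("STY")


class UnmappedPeptideError(ValueError):
    """A peptide sequence that occurs in none of the isoforms."""

    def __init__(self, peptide: str):
        self.peptide = peptide
        super().__init__(f"peptide not found in any isoform: {peptide!r}")


def load_reference_isoforms() -> dict[str, str]:
    """Load the six packaged CNS tau isoform sequences (accession -> sequence)."""
    ref = resources.files("astrotau").joinpath("data/tau_isoforms.fasta")
    with resources.as_file(ref) as path:
        return read_fasta(path)


@dataclass(frozen=True)
class SiteKey:
    """A phosphosite in canonical (2N4R, 441-residue) coordinates."""

    residue: str
    position: int

    def __post_init__(self):
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"phosphosite residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"canonical position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.residue}{self.position}"

    @classmethod
    def parse(cls, label: str) -> "SiteKey":
        return cls(label[0], int(label[1:]))

    def __lt__(self, other: "SiteKey") -> bool:
        return (self.position, self.residue) < (other.position, other.residue)


@dataclass(frozen=True)
class Block:
    """Ungapped alignment block, 1-based inclusive on both sequences."""

    isoform_start: int
    isoform_end: int
    canonical_start: int

    @property
    def length(self) -> int:
        return self.isoform_end - self.isoform_start + 1

    @property
    def canonical_end(self) -> int:
        return self.canonical_start + self.length - 1


class IsoformSet:
    """Named tau isoform sequences with a designated canonical reference."""

    def __init__(self, sequences: dict[str, str], canonical: str = CANONICAL_ACCESSION):
        if canonical not in sequences:
            raise ValueError(f"canonical accession {canonical!r} not among sequences")
        self.sequences = dict(sequences)
        self.canonical_accession = canonical

    @classmethod
    def reference(cls) -> "IsoformSet":
        return cls(load_reference_isoforms())

    @property
    def canonical_sequence(self) -> str:
        return self.sequences[self.canonical_accession]

    def __iter__(self):
        return iter(self.sequences.items())


def tryptic_peptides(sequence: str, missed_cleavages: int = 0) -> list[tuple[int, str]]:
    """Tryptic digestion: cleave after K/R except before P.

    Returns ``(start, peptide)`` pairs with 1-based starts.  With zero missed
    cleavages (the default) concatenating the peptides in order reproduces
    the input sequence exactly; ``missed_cleavages > 0`` additionally emits
    every run of up to that many adjacent fully tryptic peptides.
    """
    peptides = []
    start = 0
    for i, aa in enumerate(sequence):
        cleave = aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P")
        if cleave:
            peptides.append((start + 1, sequence[start : i + 1]))
            start = i + 1
    if start < len(sequence):
        peptides.append((start + 1, sequence[start:]))
    if missed_cleavages > 0:
        extra = []
        for i in range(len(peptides)):
            for k in range(1, missed_cleavages + 1):
                if i + k >= len(peptides):
                    break
                merged = "".join(p for _, p in peptides[i : i + k + 1])
                extra.append((peptides[i][0], merged))
        peptides = sorted(peptides + extra)
    return peptides


def build_coordinate_map(isoforms: IsoformSet) -> dict[str, list[Block]]:
    """Express each isoform as ordered ungapped blocks of the canonical sequence.

    Works greedily: from the current (isoform, canonical) offsets, extend the
    longest exact match; on mismatch, skip forward in the canonical sequence
    (a deleted exon block).  Fails if the isoform cannot be tiled this way,
    which is the case for any sequence that is not a block-deletion variant of
    the canonical isoform.
    """
    canonical = isoforms.canonical_sequence
    table: dict[str, list[Block]] = {}
    for accession, seq in isoforms:
        blocks: list[Block] = []
        i = 0  # isoform cursor (0-based)
        j = 0  # canonical cursor (0-based)
        while i < len(seq):
            # choose the canonical start (at or after the cursor) giving the
            # longest exact run; a genuine exon block beats any spurious
            # short match, and ties resolve to the leftmost start
            best_j, best_run = -1, 0
            for jj in range(j, len(canonical)):
                if canonical[jj] != seq[i]:
                    continue
                run = 1
                while (
                    i + run < len(seq)
                    and jj + run < len(canonical)
                    and seq[i + run] == canonical[jj + run]
                ):
                    run += 1
                if run > best_run:
                    best_j, best_run = jj, run
            if best_run == 0:
                raise ValueError(
                    f"isoform {accession!r} is not a block-deletion variant "
                    f"of the canonical sequence (stuck at isoform position {i + 1})"
                )
            blocks.append(Block(i + 1, i + best_run, best_j + 1))
            i += best_run
            j = best_j + best_run
        # verify: blocks tile the isoform and match the canonical substrings
        covered = sum(b.length for b in blocks)
        if covered != len(seq):
            raise ValueError(f"isoform {accession!r}: block tiling incomplete")
        for b in blocks:
            if (
                seq[b.isoform_start - 1 : b.isoform_end]
                != canonical[b.canonical_start - 1 : b.canonical_end]
            ):
                raise ValueError(f"isoform {accession!r}: block verification failed")
        table[accession] = blocks
    return table


def locate_peptide(peptide: str, isoforms: IsoformSet) -> list[tuple[str, int]]:
    """All exact occurrences of a peptide across the isoforms.

    Returns ``(accession, start)`` pairs with 1-based starts, sorted by
    accession then position.  More than one pair means the peptide is
    ambiguous (its site evidence cannot be attributed uniquely).
    """
    if not peptide:
        raise ValueError("peptide must be nonempty")
    if not peptide.isupper():
        raise ValueError("peptide must be uppercase")
    hits = []
    for accession, seq in sorted(isoforms):
        start = seq.find(peptide)
        while start != -1:
            hits.append((accession, start + 1))
            start = seq.find(peptide, start + 1)
    if not hits:
        raise UnmappedPeptideError(peptide)
    return hits


def site_to_canonical(
    accession: str,
    local_position: int,
    coord_map: dict[str, list[Block]],
    isoforms: IsoformSet,
) -> SiteKey:
    """Translate an isoform-local residue position to a canonical site label."""
    seq = isoforms.sequences[accession]
    if not 1 <= local_position <= len(seq):
        raise ValueError(
            f"position {local_position} outside isoform {accession!r} (length {len(seq)})"
        )
    for block in coord_map[accession]:
        if block.isoform_start <= local_position <= block.isoform_end:
            canonical_pos = block.canonical_start + (local_position - block.isoform_start)
            letter = isoforms.canonical_sequence[canonical_pos - 1]
            if letter != seq[local_position - 1]:
                raise ValueError(
                    f"residue mismatch mapping {accession}:{local_position} "
                    f"({seq[local_position - 1]}) to canonical {canonical_pos} ({letter})"
                )
            return SiteKey(letter, canonical_pos)
    raise ValueError(f"position {local_position} of {accession!r} outside all mapped blocks")


def canonical_to_isoform(
    site: SiteKey, accession: str, coord_map: dict[str, list[Block]]
) -> int | None:
    """Inverse mapping; ``None`` when the canonical position falls in a spliced-out block."""
    for block in coord_map[accession]:
        if block.canonical_start <= site.position <= block.canonical_end:
            return block.isoform_start + (site.position - block.canonical_start)
    return None


def phospho_candidate_sites(sequence: str) -> list[SiteKey]:
    """All S/T/Y positions of the canonical sequence, as site keys."""
    return [
        SiteKey(aa, pos)
        for pos, aa in enumerate(sequence, start=1)
        if aa in PHOSPHO_RESIDUES
    ]
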