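"""Exact-match read-to-allele alignment.

Each extracted read is matched against every allele of its gene; a read
"hits" an allele when it shares a contiguous, gapless, mismatch-free
substring of at least ``min(len(read), min_alignment_length)`` bases with it,
on either strand.  This operationalizes a local-alignment step filtered to
100% identity: the length floor suppresses spurious short exact seeds while
short reads must match end-to-end.

The implementation contract is brute-force substring scanning; the fast path
(whole-read containment check first) is an internal optimization that cannot
change results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .alleles import AlleleRecord
from .reads import ReadSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

#: Default minimum exact-match length (nt), conservative for ~100 bp WES reads.
DEFAULT_MIN_ALIGNMENT_LENGTH = 50


class AlignmentInputError(ValueError):
    """Sequence contains characters other than A, C, G, T, N."""


@dataclass
class ReadAlignments:
    """Per-gene mapping from read id to the alleles it matches exactly.

    Reads with no matching allele are dropped before the EM stage, so every
    entry's allele set is non-empty.  ``x_r`` (the per-read match count) is
    the size of the corresponding set.
    """

    gene: str
    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.entries)

    @property
    def allele_universe(self) -> list[str]:
        names: set[str] = set()
        for matched in self.entries.values():
            names |= matched
        return sorted(names)

    def x_r(self, read_id: str) -> int:
        return len(self.entries[read_id])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(seq: str, what: str) -> None:
    if not seq:
        raise AlignmentInputError(f"empty {what} sequence")
    bad = set(seq) - _VALID
    if bad:
        raise AlignmentInputError(
            f"{what} sequence contains non-nucleotide characters: {sorted(bad)}"
        )


def _has_exact_window(read: str, allele: str, k: int) -> bool:
    # A common exact substring of length >= k exists iff some k-window of
    # the read occurs verbatim in the allele.
    if read in allele:
        return True
    if k >= len(read):
        return False
    return any(read[i : i + k] in allele for i in range(len(read) - k + 1))


def match_read(
    read_sequence: str,
    allele_sequence: str,
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
) -> bool:
    """True iff the read matches the allele at 100% identity.

    The read (or its reverse complement) must share a contiguous exact
    substring of length >= ``min(len(read), min_alignment_length)`` with the
    allele.  Reads containing N never match: N equals no base under strict
    identity.
    """
    read = read_sequence.upper()
    allele = allele_sequence.upper()
    _validate(read, "read")
    _validate(allele, "allele")
    if "N" in read:
        return False
    k = min(len(read), min_alignment_length)
    if _has_exact_window(read, allele, k):
        return True
    return _has_exact_window(reverse_complement(read), allele, k)


def align_readset(
    reads: ReadSet,
    alleles: list[AlleleRecord],
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
) -> ReadAlignments:
    """Match every read in a set against a gene's allele collection.

    Reads matching no allele are omitted.  Raises a configuration error on
    an empty allele list (a gene with no database entries cannot be typed).
    """
    if not alleles:
        raise ValueError(f"no alleles supplied for gene {reads.gene}")
    entries: dict[str, frozenset[str]] = {}
    for read_id, seq in reads.reads:
        matched = frozenset(
            rec.full_name
            for rec in alleles
            if match_read(seq, rec.sequence, min_alignment_length)
        )
        if matched:
            entries[read_id] = matched
    return ReadAlignments(gene=reads.gene, entries=entries)


def write_alignments_tsv(
    alignments: Iterable[ReadAlignments], out_path: str | Path
) -> None:
    """Long-format TSV of (gene, read_id, allele_full_name)."""
    with open(out_path, "w") as fh:
        fh.write("gene\tread_id\tallele\n")
        for ra in alignments:
            for read_id in sorted(ra.entries):
                for allele in sorted(ra.entries[read_id]):
                    fh.write(f"{ra.gene}\t{read_id}\t{allele}\n")
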