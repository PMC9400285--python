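"""Optional external-BLAST alignment backend.

Shells out to ``makeblastdb``/``blastn`` with a 100% identity filter and
parses tabular output into the same :class:`~kirgeno.align.ReadAlignments`
structure the internal matcher produces.  On clean reads (no N, no indels)
the two backends agree; the internal matcher remains the reference
implementation and this backend is never required.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .align import DEFAULT_MIN_ALIGNMENT_LENGTH, ReadAlignments
from .alleles import AlleleRecord
from .reads import ReadSet


class BlastNotAvailableError(RuntimeError):
    pass


def blast_available() -> bool:
    return shutil.which("blastn") is not None and shutil.which("makeblastdb") is not None


def align_readset_blast(
    reads: ReadSet,
    alleles: list[AlleleRecord],
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
) -> ReadAlignments:
    """Match reads to alleles with blastn at 100% identity.

    A hit is kept when it is gapless, mismatch-free and its alignment length
    is at least ``min(len(read), min_alignment_length)``.
    """
    if not blast_available():
        raise BlastNotAvailableError("blastn/makeblastdb not found on PATH")
    if not alleles:
        raise ValueError(f"no alleles supplied for gene {reads.gene}")

    read_len = {rid: len(seq) for rid, seq in reads.reads}
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db_fa = tmp / "alleles.fasta"
        with open(db_fa, "w") as fh:
            for rec in alleles:
                fh.write(f">{rec.full_name}\n{rec.sequence}\n")
        reads_fa = tmp / "reads.fasta"
        with open(reads_fa, "w") as fh:
            for rid, seq in reads.reads:
                fh.write(f">{rid}\n{seq}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(db_fa), "-dbtype", "nucl"],
            check=True,
            capture_output=True,
        )
        result = subprocess.run(
            [
                "blastn",
                "-query",
                str(reads_fa),
                "-db",
                str(db_fa),
                "-perc_identity",
                "100",
                # pure exact runs: no gapped extension, stop at first mismatch
                "-ungapped",
                "-xdrop_ungap",
                "0",
                # the length floor below is the only filter we want; the
                # default e-value cutoff drops short exact HSPs on small DBs
                "-evalue",
                "1e6",
                "-outfmt",
                "6 qseqid sseqid length mismatch gapopen",
                "-dust",
                "no",
                "-max_target_seqs",
                str(len(alleles) + 10),
            ],
            check=True,
            capture_output=True,
            text=True,
        )

    entries: dict[str, set[str]] = {}
    for line in result.stdout.splitlines():
        qseqid, sseqid, length, mismatch, gapopen = line.split("\t")
        if int(mismatch) or int(gapopen):
            continue
        floor = min(read_len.get(qseqid, min_alignment_length), min_alignment_length)
        if int(length) < floor:
            continue
        entries.setdefault(qseqid, set()).add(sseqid)
    return ReadAlignments(
        gene=reads.gene,
        entries={rid: frozenset(names) for rid, names in entries.items()},
    )
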