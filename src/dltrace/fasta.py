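"""FASTA input: the first record of a file, as a plain string."""

from __future__ import annotations

import os

from Bio import SeqIO

__all__ = ["read_fasta_first_record"]


def read_fasta_first_record(path: str) -> str:
    """Sequence of the first FASTA record (multi-line records concatenated).

    Description text after the identifier is ignored; case is preserved.
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for an
    empty file or one whose first non-blank line is not a '>' header.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        head = ""
        for line in fh:
            if line.strip():
                head = line
                break
        if not head:
            raise ValueError(f"{path}: empty FASTA file")
        if not head.lstrip().startswith(">"):
            raise ValueError(f"{path}: malformed FASTA, first line is not a '>' header")
    record = next(SeqIO.parse(path, "fasta"), None)
    if record is None:
        raise ValueError(f"{path}: no FASTA records found")
    return str(record.seq)
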