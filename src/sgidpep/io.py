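"""Reading and writing peptide pools: FASTA and plain-text sequence lists.

FASTA headers carry the pool metadata as ``name|source|alc=NN.N`` (the ALC
field is omitted for unscored peptides). Plain-text input is one sequence per
line with an optional tab-separated ALC column.
"""

from __future__ import annotations

import os
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Peptide, PeptidePool, Source, validate_sequence

PathLike = Union[str, os.PathLike]


def _record_id(name: str, index: int, peptide: Peptide) -> str:
    head = f"{name}_{index}|{peptide.source.value}"
    if peptide.alc is not None:
        head += f"|alc={peptide.alc:.1f}"
    return head


def write_fasta(pool: PeptidePool, path: PathLike) -> None:
    """Write a pool as FASTA, one record per peptide, 60-column wrapped."""
    records = [
        SeqRecord(Seq(p.sequence), id=_record_id(pool.name, i + 1, p), description="")
        for i, p in enumerate(pool)
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_header(header: str) -> tuple:
    source = Source.SYNTHETIC
    alc: Optional[float] = None
    for part in header.split("|")[1:]:
        part = part.strip()
        if part.startswith("alc="):
            alc = float(part[4:])
        else:
            try:
                source = Source(part)
            except ValueError:
                pass
    return source, alc


def read_fasta(path: PathLike, name: Optional[str] = None,
               source: Optional[Source] = None) -> PeptidePool:
    """Read a FASTA file into a :class:`PeptidePool`.

    Source and ALC are recovered from ``name|source|alc=NN.N`` headers when
    present; ``source`` overrides the header for every record.
    """
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        hdr_source, alc = _parse_header(rec.id)
        peptides.append(
            validate_sequence(str(rec.seq), source=source or hdr_source, alc=alc)
        )
    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return PeptidePool(name, peptides)


def read_text(path: PathLike, name: Optional[str] = None,
              source: Source = Source.SYNTHETIC) -> PeptidePool:
    """Read one-sequence-per-line text, with an optional tab-separated ALC
    column, into a :class:`PeptidePool`. Blank lines and ``#`` comments are
    skipped."""
    peptides = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            alc = float(fields[1]) if len(fields) > 1 and fields[1] else None
            peptides.append(validate_sequence(fields[0], source=source, alc=alc))
    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return PeptidePool(name, peptides)


def read_pool(path: PathLike, name: Optional[str] = None,
              source: Optional[Source] = None) -> PeptidePool:
    """Dispatch on extension: ``.fasta``/``.fa``/``.faa`` → FASTA, else text."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".fasta", ".fa", ".faa"}:
        return read_fasta(path, name=name, source=source)
    return read_text(path, name=name, source=source or Source.SYNTHETIC)
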