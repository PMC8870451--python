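"""Aligned sequence sets and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {GAP, "X"}


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Equal-length aligned residue strings with optional taxon labels."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    taxa: tuple[str, ...] | None = None  # phylum / clade label per sequence

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment is empty")
        if len(self.ids) != len(self.sequences):
            raise ValueError("one sequence per id required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences must share one length, got {sorted(lengths)}")
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq.upper()) - ALPHABET
            if bad:
                raise ValueError(f"sequence {sid!r}: illegal characters {sorted(bad)}")
        if self.taxa is not None and len(self.taxa) != len(self.ids):
            raise ValueError("one taxon label per sequence required")
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def sequence(self, sid: str) -> str:
        return self.sequences[self.ids.index(sid)]

    def subset(self, keep_ids) -> "AlignedSequenceSet":
        keep = [self.ids.index(i) for i in keep_ids]
        return AlignedSequenceSet(
            ids=tuple(self.ids[i] for i in keep),
            sequences=tuple(self.sequences[i] for i in keep),
            taxa=tuple(self.taxa[i] for i in keep) if self.taxa is not None else None,
        )

    def ungapped_length(self, sid: str) -> int:
        return sum(1 for c in self.sequence(sid) if c != GAP)


def read_fasta(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA; a taxon may be encoded as 'id|taxon' in headers."""
    ids, seqs, taxa = [], [], []
    any_taxon = False
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        if "|" in header:
            sid, taxon = header.split("|", 1)
            any_taxon = True
        else:
            sid, taxon = header, ""
        ids.append(sid)
        taxa.append(taxon)
        seqs.append(str(record.seq))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    return AlignedSequenceSet(
        ids=tuple(ids),
        sequences=tuple(seqs),
        taxa=tuple(taxa) if any_taxon else None,
    )


def write_fasta(aln: AlignedSequenceSet, path: str | Path) -> None:
    records = []
    for i, (sid, seq) in enumerate(zip(aln.ids, aln.sequences)):
        header = sid if aln.taxa is None else f"{sid}|{aln.taxa[i]}"
        records.append(SeqRecord(Seq(seq), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")
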