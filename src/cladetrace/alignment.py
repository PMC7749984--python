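"""Multiple sequence alignment container and FASTA I/O."""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError

ALPHABET = frozenset("ACGTN-")


class Alignment:
    """Ordered, equal-length DNA sequences over ``{A,C,G,T,N,-}``.

    Names must be unique; order is preserved as given.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        recs = [(str(name), str(seq).upper()) for name, seq in records]
        if not recs:
            raise AlignmentError("alignment must contain at least one sequence")
        names = [n for n, _ in recs]
        if len(set(names)) != len(names):
            raise AlignmentError("duplicate sequence names in alignment")
        length = len(recs[0][1])
        for name, seq in recs:
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence {name!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {name!r} contains invalid symbols {sorted(bad)}"
                )
        self._records = recs
        self._index = {name: seq for name, seq in recs}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self._records)

    @property
    def length(self) -> int:
        return len(self._records[0][1])

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._records)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def get(self, name: str) -> str:
        try:
            return self._index[name]
        except KeyError:
            raise AlignmentError(f"no sequence named {name!r}") from None

    def subset(self, names: Iterable[str]) -> "Alignment":
        """Sub-alignment with the given names, in the given order."""
        return Alignment([(n, self.get(n)) for n in names])

    # -- FASTA --------------------------------------------------------------

    def to_fasta(self, path=None) -> str:
        """Write plain FASTA (80-column wrapping); return the text."""
        buf = io.StringIO()
        writer = FastaWriter(buf, wrap=80)
        writer.write_file(
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self._records
        )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        """Read from a path or file handle."""
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                recs = list(SeqIO.parse(fh, "fasta"))
        else:
            recs = list(SeqIO.parse(source, "fasta"))
        return cls([(r.id, str(r.seq)) for r in recs])
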