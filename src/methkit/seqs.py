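"""Reference-sequence access and motif scanning shared across modules."""

from __future__ import annotations

import re
from typing import Mapping, Union

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")

#: IUPAC nucleotide codes as regex character classes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_regex(motif: str) -> "re.Pattern":
    """Compile an IUPAC motif into an overlapping-match (lookahead) regex."""
    try:
        body = "".join(IUPAC[c] for c in motif.upper())
    except KeyError as e:
        raise ValueError(f"invalid IUPAC code in motif {motif!r}: {e}") from None
    return re.compile(f"(?={body})")


def motif_positions(seq: str, motif: str, offset: int = 0) -> np.ndarray:
    """0-based positions of ``match start + offset`` for every motif match.

    Overlapping matches are all reported; positions are strictly increasing.
    """
    if len(motif) < 1:
        raise ValueError("motif must be non-empty")
    if not 0 <= offset < len(motif):
        raise ValueError(f"offset {offset} outside motif of length {len(motif)}")
    pat = motif_regex(motif)
    return np.array([m.start() + offset for m in pat.finditer(seq.upper())], dtype=int)


class Reference:
    """Uniform fetch interface over a FASTA path, pyfaidx.Fasta, or dict."""

    def __init__(self, source: Union[str, Mapping]):
        if isinstance(source, (str,)):
            import pyfaidx

            self._fa = pyfaidx.Fasta(str(source))
            self._dict = None
        elif isinstance(source, Reference):
            self._fa, self._dict = source._fa, source._dict
        else:
            self._fa, self._dict = None, source

    def chrom_length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fa[chrom])

    @property
    def chroms(self) -> list:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fa.keys())

    def fetch(self, chrom: str, start: int = 0, end: int = None) -> str:
        n = self.chrom_length(chrom)
        if end is None:
            end = n
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"region {chrom}:{start}-{end} outside reference (length {n})"
            )
        if self._dict is not None:
            return str(self._dict[chrom][start:end]).upper()
        return str(self._fa[chrom][start:end]).upper()
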