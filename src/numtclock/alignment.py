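"""Aligned sequence container and per-site conservation score table.

Sequences are over the alphabet {A, C, G, T, -, N}; gaps and Ns are treated
as missing data throughout the pipeline.  FASTA input/output is delegated to
Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Integer codes used internally: A=0, C=1, G=2, T=3, missing (gap or N)=4.
NUC_CODES: Mapping[str, int] = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 4}
CODE_TO_NUC = np.array(["A", "C", "G", "T", "-"])
MISSING = 4


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with stable identifiers.

    Parameters
    ----------
    ids
        Sequence identifiers, in display order.
    data
        Character matrix of shape ``(n_sequences, n_columns)``, dtype ``<U1``.
    numt_id
        Identifier of the sequence tagged as the NUMT, if any.
    """

    ids: list[str]
    data: np.ndarray
    numt_id: str | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="U1")
        if self.data.ndim != 2:
            raise AlignmentError("alignment data must be a 2-D character matrix")
        if len(self.ids) != self.data.shape[0]:
            raise AlignmentError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence identifiers")
        bad = ~np.isin(self.data, list(NUC_CODES))
        if bad.any():
            raise AlignmentError(
                f"invalid characters in alignment: {sorted(set(self.data[bad]))}"
            )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_sequences(
        cls, seqs: Mapping[str, str] | Iterable[tuple[str, str]], numt_id: str | None = None
    ) -> "Alignment":
        items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
        if not items:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [i for i, _ in items]
        data = np.array([list(s.upper()) for _, s in items], dtype="U1")
        return cls(ids=ids, data=data, numt_id=numt_id)

    @classmethod
    def read_fasta(cls, path: str | Path, numt_id: str | None = None) -> "Alignment":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        aln = cls.from_sequences(records, numt_id=numt_id)
        if numt_id is None:
            # convention: a sequence whose id starts with "NUMT" is the NUMT
            tagged = [i for i in aln.ids if i.upper().startswith("NUMT")]
            if len(tagged) == 1:
                aln.numt_id = tagged[0]
        return aln

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=sid, description="")
            for sid, row in zip(self.ids, self.data)
        ]
        SeqIO.write(records, str(path), "fasta")

    # -- access ------------------------------------------------------------
    @property
    def n_seqs(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def sequence(self, sid: str) -> str:
        return "".join(self.data[self.ids.index(sid)])

    def encoded(self) -> np.ndarray:
        """Integer-coded matrix (A=0 C=1 G=2 T=3, missing=4), cached."""
        if self._codes is None:
            codes = np.empty(self.data.shape, dtype=np.int8)
            for ch, code in NUC_CODES.items():
                codes[self.data == ch] = code
            self._codes = codes
        return self._codes

    def row(self, sid: str) -> np.ndarray:
        return self.encoded()[self.ids.index(sid)]

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """Sub-alignment keeping ``columns`` (0-based), order preserved."""
        cols = np.asarray(columns, dtype=int)
        return Alignment(ids=list(self.ids), data=self.data[:, cols], numt_id=self.numt_id)

    def drop_columns(self, columns: Sequence[int]) -> "Alignment":
        mask = np.ones(self.n_columns, dtype=bool)
        mask[np.asarray(columns, dtype=int)] = False
        return Alignment(ids=list(self.ids), data=self.data[:, mask], numt_id=self.numt_id)


@dataclass
class SiteScoreTable:
    """Per-position conservation scores (GERP-style) for a reference sequence.

    Scores are attached to 1-based reference positions.  Low scores mark
    evolutionarily conserved positions, high scores variable ones.  The
    two-bin classification (conserved / variable) uses the midpoint of the
    declared score range as boundary; the boundary value itself falls in the
    "variable" bin.
    """

    positions: np.ndarray  # 1-based
    scores: np.ndarray
    range_low: float = -9.75
    range_high: float = 4.87

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.positions.shape != self.scores.shape:
            raise ValueError("positions and scores must have equal length")
        if self.range_low >= self.range_high:
            raise ValueError("score range is empty")

    @property
    def boundary(self) -> float:
        return (self.range_low + self.range_high) / 2.0

    def score_at(self, pos: int) -> float | None:
        idx = np.searchsorted(self.positions, pos)
        if idx < len(self.positions) and self.positions[idx] == pos:
            return float(self.scores[idx])
        return None

    def bins(self) -> np.ndarray:
        """Array of "conserved"/"variable" labels, aligned with ``positions``."""
        return np.where(self.scores < self.boundary, "conserved", "variable")

    @classmethod
    def read_tsv(
        cls, path: str | Path, range_low: float = -9.75, range_high: float = 4.87
    ) -> "SiteScoreTable":
        df = pd.read_csv(path, sep="\t")
        if not {"pos", "score"} <= set(df.columns):
            raise ValueError("score table must have columns 'pos' and 'score'")
        order = np.argsort(df["pos"].to_numpy())
        return cls(
            positions=df["pos"].to_numpy()[order],
            scores=df["score"].to_numpy()[order],
            range_low=range_low,
            range_high=range_high,
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"pos": self.positions, "score": self.scores}).to_csv(
            path, sep="\t", index=False
        )
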