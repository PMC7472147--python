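"""Shared domain records: reads, contigs, protein-database entries and
translated-alignment hits.

These are deliberately plain dataclasses — every module consumes and produces
them, and keeping them free of behaviour avoids import cycles between the
pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class Read:
    """A sequencing read: bases over {A,C,G,T,N} plus per-base Phred scores.

    ``quals`` is stored as a uint8 array of the same length as ``bases``.
    ``mate`` optionally names the paired read.
    """

    id: str
    bases: str
    quals: np.ndarray
    mate: Optional[str] = None

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.bases) != self.quals.shape[0]:
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {self.quals.shape[0]} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Contig:
    """An assembled contig with its supporting reads and mean coverage."""

    id: str
    bases: str
    support: list = field(default_factory=list)
    mean_coverage: float = 0.0
    circular: bool = False
    #: set for degenerate sequences (e.g. homopolymers) where terminal-repeat
    #: circularity cannot be decided
    circularity_ambiguous: bool = False

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ProteinDbRecord:
    """A reference protein labelled virus / nonvirus for best-hit arbitration."""

    id: str
    residues: str
    label: str  # "virus" | "nonvirus"
    taxon: str
    family: Optional[str] = None

    def __post_init__(self):
        if self.label not in ("virus", "nonvirus"):
            raise ValueError(f"record {self.id}: label must be virus|nonvirus, got {self.label!r}")


@dataclass
class AlignmentHit:
    """A frame-aware translated local alignment of a nucleotide query against
    a protein subject.

    ``query_interval`` is in 0-based half-open nucleotide coordinates on the
    forward strand of the query; ``subject_interval`` is in residue
    coordinates.  ``bit_score = (lambda*raw - ln K) / ln 2``.
    """

    query_id: str
    frame: int  # +1..+3, -1..-3
    query_interval: tuple
    subject_id: str
    subject_interval: tuple
    raw_score: float
    bit_score: float
    evalue: float
    percent_identity: float
    subject_label: Optional[str] = None
    subject_taxon: Optional[str] = None
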