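"""Core domain types.

A contig is a contiguous assembled sequence; its predicted genes (CDS
intervals from a prokaryotic gene caller run in metagenomic mode) are the
raw material for every downstream feature.  Coordinates follow the GFF3
convention throughout: 1-based, fully inclusive, never converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .exceptions import CoordinateMismatchError, ParameterError

EUKARYOTE = "eukaryote"
PROKARYOTE = "prokaryote"
CLASS_LABELS = (EUKARYOTE, PROKARYOTE)

#: Unicode minus occasionally appears in copy-pasted annotation tables.
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


def normalize_strand(symbol: str) -> str:
    """Map a strand symbol to ASCII ``+``/``-``; reject anything else."""
    try:
        return _STRAND_ALIASES[symbol]
    except KeyError:
        raise ParameterError(f"invalid strand symbol: {symbol!r}") from None


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One predicted gene on a contig.

    ``start``/``end`` are 1-based inclusive base-pair positions;
    ``has_rbs`` records whether the gene caller reported a
    ribosome-binding-site motif upstream of the gene.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    has_rbs: bool = False
    gene_index: int = 0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ParameterError(f"gene start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ParameterError(
                f"gene end {self.end} < start {self.start} on {self.contig_id}"
            )
        object.__setattr__(self, "strand", normalize_strand(self.strand))

    @property
    def length(self) -> int:
        """Gene length as end − start (the convention used by the features)."""
        return self.end - self.start

    def shifted(self, offset: int, contig_id: Optional[str] = None) -> "GeneRecord":
        """Return a copy with coordinates shifted by ``offset`` base pairs."""
        return replace(
            self,
            contig_id=contig_id if contig_id is not None else self.contig_id,
            start=self.start + offset,
            end=self.end + offset,
        )


@dataclass(slots=True)
class ContigAnnotation:
    """A contig's length plus its ordered gene records.

    ``label`` (eukaryote/prokaryote) and ``organism_id`` (the grouping key
    for organism-grouped cross-validation) are populated for training data
    only.
    """

    contig_id: str
    length: Optional[int]
    genes: list[GeneRecord] = field(default_factory=list)
    label: Optional[str] = None
    organism_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        self.validate()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        """Check internal consistency; raise on violation."""
        for g in self.genes:
            if g.contig_id != self.contig_id:
                raise ParameterError(
                    f"gene contig id {g.contig_id!r} != contig {self.contig_id!r}"
                )
        if self.length is not None:
            if self.length < 0:
                raise ParameterError(f"negative contig length on {self.contig_id}")
            for g in self.genes:
                if g.end > self.length:
                    raise CoordinateMismatchError(
                        f"gene ending at {g.end} exceeds length {self.length} "
                        f"of contig {self.contig_id}"
                    )
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ParameterError(f"unknown class label {self.label!r}")


@dataclass(frozen=True, slots=True)
class TiaraPrediction:
    """An external k-mer classifier's call for one contig.

    ``code`` is the three-level categorical encoding used as the extra
    feature of the enhanced model: 0 = eukaryotic call, 1 = prokaryotic
    call (prokarya/bacteria/archaea), 2 = unknown or organelle.
    """

    contig_id: str
    class_string: str
    code: int

    def __post_init__(self) -> None:
        if self.code not in (0, 1, 2):
            raise ParameterError(f"tiara code must be 0, 1 or 2, got {self.code}")


@dataclass(frozen=True, slots=True)
class ContigFeatures:
    """The per-contig gene-structure feature vector.

    Intergenic-distance summaries may be negative (overlapping genes);
    the two ratios live in [0, 1].  ``tiara_code`` is present only for the
    enhanced model variant.
    """

    contig_id: str
    n_genes: int
    ig_mean: float
    ig_std: float
    ig_q1: float
    ig_q3: float
    gene_density: float
    mean_gene_length: float
    same_strand_ratio: float
    rbs_ratio: float
    tiara_code: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ParameterError("features require at least 2 genes")
        if self.ig_q1 > self.ig_q3:
            raise ParameterError("first quartile exceeds third quartile")
        for name in ("same_strand_ratio", "rbs_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} out of [0, 1]: {v}")


def check_same_schema(rows: Sequence[ContigFeatures]) -> bool:
    """True iff all rows agree on the presence/absence of the tiara code."""
    if not rows:
        return True
    has = rows[0].tiara_code is not None
    return all((r.tiara_code is not None) == has for r in rows)
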