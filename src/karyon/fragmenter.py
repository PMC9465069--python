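"""Split whole genome assemblies into artificial contigs.

Training data for the classifier is built by fragmenting reference
genomes into non-overlapping pieces whose lengths follow a triangular
distribution on [5 kb, 100 kb] with mode 10 kb, mimicking contig sizes
in real metagenome assemblies.  Non-nuclear sequences (organelles,
plastids, apicoplasts) are removed by header keywords first, and at most
500 fragments per genome are kept so large eukaryotic genomes do not
dominate the training set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import ParameterError
from .types import ContigAnnotation, GeneRecord


@dataclass(frozen=True, slots=True)
class TriangularParams:
    """Triangular length distribution: lower limit, mode, upper limit (bp)."""

    lower: int = 5000
    mode: int = 10000
    upper: int = 100000

    def __post_init__(self) -> None:
        if not self.lower <= self.mode <= self.upper:
            raise ParameterError(
                f"require lower <= mode <= upper, got "
                f"({self.lower}, {self.mode}, {self.upper})"
            )
        if self.lower < 1:
            raise ParameterError("lower limit must be positive")

    @property
    def analytic_mean(self) -> float:
        return (self.lower + self.mode + self.upper) / 3.0


@dataclass(frozen=True, slots=True)
class FragmentSpec:
    """One artificial contig cut from a source sequence.

    ``offset`` is 0-based within the source; the fragment covers source
    positions [offset+1, offset+length] in 1-based coordinates.
    """

    source_id: str
    source_organism: str
    offset: int
    length: int
    fragment_id: str

    def __post_init__(self) -> None:
        if self.offset < 0 or self.length < 1:
            raise ParameterError("fragment offset/length out of range")


@dataclass
class FragmentationResult:
    fragments: list[FragmentSpec]
    #: (source_id, offset, length) of terminal remainders too short to keep.
    discarded: list[tuple[str, int, int]]
    #: fragments removed by the per-genome cap subsampling.
    n_capped: int = 0


#: Header keywords marking non-nuclear sequences.  The full words are
#: matched case-insensitively as substrings; the short accession codes
#: "API" and "MIT" only as standalone uppercase tokens, so that e.g.
#: "mitigated" or "capital" never match.
NONNUCLEAR_WORDS: tuple[str, ...] = (
    "mitochondrial",
    "plastid",
    "chloroplast",
    "mitochondrion",
    "non-nuclear",
    "organelle",
    "apicoplast",
)
NONNUCLEAR_CODES: tuple[str, ...] = ("API", "MIT")

_TOKEN_RE = re.compile(r"[A-Za-z0-9-]+")


def is_nonnuclear_header(header: str) -> bool:
    low = header.lower()
    if any(word in low for word in NONNUCLEAR_WORDS):
        return True
    tokens = set(_TOKEN_RE.findall(header))
    return any(code in tokens for code in NONNUCLEAR_CODES)


def filter_nonnuclear(headers: Sequence[str]) -> tuple[list[str], list[str]]:
    """Partition headers into (kept, dropped) by the non-nuclear keywords."""
    kept, dropped = [], []
    for h in headers:
        (dropped if is_nonnuclear_header(h) else kept).append(h)
    return kept, dropped


def sample_fragment_length(
    params: TriangularParams, rng: np.random.Generator
) -> int:
    """Draw one fragment length (bp) from the triangular distribution."""
    if params.lower == params.upper:
        return params.lower
    draw = rng.triangular(params.lower, params.mode, params.upper)
    return int(min(max(round(draw), params.lower), params.upper))


def fragment_genome(
    record_lengths: Mapping[str, int],
    organism: str,
    params: Optional[TriangularParams] = None,
    cap: int = 500,
    rng: Optional[np.random.Generator] = None,
) -> FragmentationResult:
    """Tile each source sequence left-to-right with sampled fragment lengths.

    The length of each fragment is drawn before checking the remaining
    sequence; when the draw exceeds what is left, the remainder becomes
    the terminal piece, kept only if it reaches the lower length limit.
    If the genome yields more than ``cap`` fragments, a seeded uniform
    subsample of exactly ``cap`` is retained (order preserved).
    """
    if cap < 1:
        raise ParameterError(f"cap must be >= 1, got {cap}")
    params = params or TriangularParams()
    rng = rng if rng is not None else np.random.default_rng()

    fragments: list[FragmentSpec] = []
    discarded: list[tuple[str, int, int]] = []
    for source_id, total in record_lengths.items():
        pos = 0
        k = 0
        while pos < total:
            draw = sample_fragment_length(params, rng)
            length = min(draw, total - pos)
            if length < params.lower:
                discarded.append((source_id, pos, length))
                break
            fragments.append(
                FragmentSpec(
                    source_id=source_id,
                    source_organism=organism,
                    offset=pos,
                    length=length,
                    fragment_id=f"{source_id}_frag{k}",
                )
            )
            pos += length
            k += 1

    n_capped = 0
    if len(fragments) > cap:
        n_capped = len(fragments) - cap
        idx = rng.choice(len(fragments), size=cap, replace=False)
        fragments = [fragments[i] for i in sorted(idx)]
    return FragmentationResult(fragments, discarded, n_capped)


def remap_reference_annotation(
    genes: Sequence[GeneRecord], fragment: FragmentSpec
) -> list[GeneRecord]:
    """Shift source-coordinate genes onto a fragment.

    Genes fully contained in the fragment window are kept with
    fragment-relative 1-based coordinates; genes straddling a boundary
    are dropped.
    """
    lo = fragment.offset + 1
    hi = fragment.offset + fragment.length
    kept = [g for g in genes if g.start >= lo and g.end <= hi]
    return [
        GeneRecord(
            contig_id=fragment.fragment_id,
            start=g.start - fragment.offset,
            end=g.end - fragment.offset,
            strand=g.strand,
            has_rbs=g.has_rbs,
            gene_index=i,
        )
        for i, g in enumerate(kept)
    ]


def fragment_annotation(
    source: ContigAnnotation, fragment: FragmentSpec
) -> ContigAnnotation:
    """Build the annotation of one fragment from its source's annotation."""
    return ContigAnnotation(
        contig_id=fragment.fragment_id,
        length=fragment.length,
        genes=remap_reference_annotation(source.genes, fragment),
        label=source.label,
        organism_id=source.organism_id or fragment.source_organism,
    )
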