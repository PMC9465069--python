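"""Synthetic labelled contigs with eukaryote-like or prokaryote-like gene
structure.

The generator lays genes down left to right, alternating a sampled
intergenic gap (exponential, occasionally replaced by a small negative
overlap) with a sampled gene length (log-normal, floored at 90 bp).
Strand follows a two-state Markov chain whose persistence models operon
co-orientation; RBS flags are independent coin flips.  Each synthetic
"organism" draws its own parameters by multiplicative log-normal jitter
around its class preset, so grouped cross-validation has real groups.

The presets reproduce the qualitative contrasts seen between real
eukaryotic and prokaryotic contigs — prokaryotes: short gaps, high gene
density, long genes, strand-coherent, RBS-rich; eukaryotes (as seen by a
prokaryotic gene caller, which tends to call a gene per exon): long
gaps, sparse short genes, weak strand coherence, few RBS motifs.  They
are fixture constants, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import ParameterError
from .features import encode_tiara
from .fragmenter import TriangularParams, sample_fragment_length
from .types import (
    ContigAnnotation,
    EUKARYOTE,
    GeneRecord,
    PROKARYOTE,
    TiaraPrediction,
)

MIN_GENE_LENGTH = 90  # bp; floor for sampled gene lengths
MAX_OVERLAP = 200  # bp; negative gaps are bounded below by -MAX_OVERLAP


@dataclass(frozen=True, slots=True)
class StructureParams:
    """Generative parameters of one contig class (all lengths in bp)."""

    label: str
    ig_mean_bp: float
    gene_len_mean_bp: float
    gene_len_sd_bp: float
    strand_persistence: float
    rbs_prob: float
    overlap_prob: float

    def __post_init__(self) -> None:
        if self.ig_mean_bp <= 0 or self.gene_len_mean_bp <= 0:
            raise ParameterError("means must be positive")
        if self.gene_len_sd_bp < 0:
            raise ParameterError("gene length SD must be >= 0")
        for name in ("strand_persistence", "rbs_prob", "overlap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} out of [0, 1]: {v}")


PROKARYOTE_PRESET = StructureParams(
    label=PROKARYOTE,
    ig_mean_bp=120.0,
    gene_len_mean_bp=900.0,
    gene_len_sd_bp=300.0,
    strand_persistence=0.8,
    rbs_prob=0.7,
    overlap_prob=0.15,
)
EUKARYOTE_PRESET = StructureParams(
    label=EUKARYOTE,
    ig_mean_bp=1500.0,
    gene_len_mean_bp=600.0,
    gene_len_sd_bp=350.0,
    strand_persistence=0.55,
    rbs_prob=0.3,
    overlap_prob=0.02,
)
DEFAULT_PRESETS = {PROKARYOTE: PROKARYOTE_PRESET, EUKARYOTE: EUKARYOTE_PRESET}


@dataclass
class SyntheticDataset:
    contigs: list[ContigAnnotation]
    params_used: dict[str, list[StructureParams]]
    seed: int

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.contigs]

    @property
    def organism_ids(self) -> list[str]:
        return [c.organism_id for c in self.contigs]


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _sample_gap(params: StructureParams, rng: np.random.Generator) -> int:
    if params.overlap_prob > 0 and rng.random() < params.overlap_prob:
        return -int(rng.integers(1, MAX_OVERLAP + 1))
    return int(round(rng.exponential(params.ig_mean_bp)))


def _lay_genes(
    params: StructureParams,
    target_length: int,
    rng: np.random.Generator,
    contig_id: str,
) -> list[GeneRecord]:
    mu, sigma = _lognormal_mu_sigma(params.gene_len_mean_bp, params.gene_len_sd_bp)
    genes: list[GeneRecord] = []
    strand = "+" if rng.random() < 0.5 else "-"
    pos = 1
    while True:
        gap = _sample_gap(params, rng)
        start = pos + gap
        if genes:
            start = max(start, genes[-1].start + 1)  # keep positional order
        start = max(start, 1)
        length = max(MIN_GENE_LENGTH, int(round(rng.lognormal(mu, sigma))))
        end = start + length  # gene length convention: end - start
        if end > target_length:
            break
        if genes and rng.random() >= params.strand_persistence:
            strand = "-" if strand == "+" else "+"
        genes.append(
            GeneRecord(
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                has_rbs=bool(rng.random() < params.rbs_prob),
                gene_index=len(genes),
            )
        )
        pos = end
    return genes


def generate_contig(
    params: StructureParams,
    target_length: int,
    rng: np.random.Generator,
    contig_id: str = "synthetic_contig",
    organism_id: Optional[str] = None,
) -> ContigAnnotation:
    """Generate one annotated contig of the given length.

    At least two genes are guaranteed: after a few failed attempts the
    intergenic gap mean is halved and generation retried; a target too
    short to ever hold two minimal genes raises :class:`ParameterError`.
    """
    if target_length < 2 * (MIN_GENE_LENGTH + 1) + 1:
        raise ParameterError(
            f"target length {target_length} too short for two genes"
        )
    current = params
    for _shrink in range(16):
        for _attempt in range(5):
            genes = _lay_genes(current, target_length, rng, contig_id)
            if len(genes) >= 2:
                return ContigAnnotation(
                    contig_id=contig_id,
                    length=target_length,
                    genes=genes,
                    label=params.label,
                    organism_id=organism_id,
                )
        current = replace(current, ig_mean_bp=max(current.ig_mean_bp / 2, 1.0))
    raise ParameterError(
        f"could not place two genes on a {target_length} bp contig"
    )


def _jittered(
    params: StructureParams, jitter: float, rng: np.random.Generator
) -> StructureParams:
    if jitter == 0:
        return params

    def scale() -> float:
        return float(rng.lognormal(0.0, jitter))

    def clip01(x: float) -> float:
        return float(min(max(x, 0.01), 0.99))

    return replace(
        params,
        ig_mean_bp=params.ig_mean_bp * scale(),
        gene_len_mean_bp=params.gene_len_mean_bp * scale(),
        gene_len_sd_bp=params.gene_len_sd_bp * scale(),
        strand_persistence=clip01(params.strand_persistence * scale()),
        rbs_prob=clip01(params.rbs_prob * scale()),
        overlap_prob=clip01(params.overlap_prob * scale()) if params.overlap_prob > 0 else 0.0,
    )


def generate_dataset(
    n_organisms_per_class: int = 10,
    contigs_per_organism: int = 20,
    length_params: Optional[TriangularParams] = None,
    presets: Optional[dict[str, StructureParams]] = None,
    jitter: float = 0.15,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a labelled, organism-grouped dataset of annotated contigs.

    Each synthetic organism receives its own jittered parameter draw
    around its class preset; contig lengths follow the triangular
    distribution used for genome fragmentation.  Fully deterministic
    given the seed.
    """
    if n_organisms_per_class < 2:
        raise ParameterError("need >= 2 organisms per class for grouped CV")
    if contigs_per_organism < 1:
        raise ParameterError("need >= 1 contig per organism")
    if jitter < 0:
        raise ParameterError(f"jitter must be >= 0, got {jitter}")
    length_params = length_params or TriangularParams()
    presets = presets or DEFAULT_PRESETS

    rng = np.random.default_rng(seed)
    contigs: list[ContigAnnotation] = []
    params_used: dict[str, list[StructureParams]] = {}
    for label in sorted(presets):
        preset = presets[label]
        params_used[label] = []
        for o in range(n_organisms_per_class):
            organism_id = f"{label[:3]}_org{o:02d}"
            org_params = _jittered(preset, jitter, rng)
            params_used[label].append(org_params)
            for c in range(contigs_per_organism):
                length = sample_fragment_length(length_params, rng)
                contigs.append(
                    generate_contig(
                        org_params,
                        length,
                        rng,
                        contig_id=f"{organism_id}_c{c:03d}",
                        organism_id=organism_id,
                    )
                )
    return SyntheticDataset(contigs=contigs, params_used=params_used, seed=seed)


_TIARA_STRINGS = {EUKARYOTE: "eukarya", PROKARYOTE: "prokarya"}


def synthetic_tiara(
    contigs: Sequence[ContigAnnotation],
    error_rate: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> list[TiaraPrediction]:
    """Label-correlated stand-in for an external k-mer classifier's calls.

    Each contig gets the class string matching its true label; with
    probability ``error_rate`` the call is corrupted to either the
    opposite class or "unknown" (equally likely).  This is a synthetic
    construct for end-to-end testing, not an emulation of any real
    classifier's error structure.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ParameterError(f"error_rate out of [0, 1]: {error_rate}")
    rng = rng if rng is not None else np.random.default_rng()
    preds = []
    for c in contigs:
        if c.label is None:
            raise ParameterError(f"contig {c.contig_id} has no label")
        cls = _TIARA_STRINGS[c.label]
        if rng.random() < error_rate:
            other = _TIARA_STRINGS[EUKARYOTE if c.label == PROKARYOTE else PROKARYOTE]
            cls = other if rng.random() < 0.5 else "unknown"
        preds.append(TiaraPrediction(c.contig_id, cls, encode_tiara(cls)))
    return preds


_BASES = np.array(list("ACGT"))


def write_dataset(
    dataset: SyntheticDataset,
    outdir,
    write_fasta: bool = True,
    tiara: Optional[Sequence[TiaraPrediction]] = None,
) -> dict[str, Path]:
    """Write a dataset as GFF + manifest (+ FASTA, + external-call table).

    The FASTA holds uniform-random nucleotide sequence of the right
    lengths (sequence content is irrelevant to this method); the manifest
    records contig id, label, organism id, length and gene count, plus
    the generation seed in its header comment.
    """
    from . import annotation_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff": outdir / "annotations.gff",
        "manifest": outdir / "manifest.tsv",
    }
    annotation_io.write_gff(dataset.contigs, paths["gff"])
    with paths["manifest"].open("w") as fh:
        fh.write(f"# seed={dataset.seed}\n")
        fh.write("contig_id\tlabel\torganism_id\tlength\tn_genes\n")
        for c in dataset.contigs:
            fh.write(
                f"{c.contig_id}\t{c.label}\t{c.organism_id}\t{c.length}\t{c.n_genes}\n"
            )
    if write_fasta:
        paths["fasta"] = outdir / "contigs.fasta"
        rng = np.random.default_rng(dataset.seed + 1)
        with paths["fasta"].open("w") as fh:
            for c in dataset.contigs:
                seq = "".join(_BASES[rng.integers(0, 4, size=c.length)])
                fh.write(f">{c.contig_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    if tiara is not None:
        paths["tiara"] = outdir / "tiara.tsv"
        with paths["tiara"].open("w") as fh:
            fh.write("sequence_id\tclass_fst_stage\n")
            for p in tiara:
                fh.write(f"{p.contig_id}\t{p.class_string}\n")
    return paths
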