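"""Readers and writers for the external formats the tool touches.

GFF3 as produced by Prodigal (CDS features, ``rbs_motif`` attribute,
``# Sequence Data: ...;seqlen=...`` comments), FASTA via Biopython,
tab-separated feature / prediction / Tiara tables via pandas.

Warnings raised while parsing are collected in a :class:`ParseReport`
rather than printed, so library use stays silent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .exceptions import (
    CoordinateMismatchError,
    DuplicateIdError,
    GFFParseError,
    MissingLengthError,
    SchemaError,
)
from .features import MODEL_FEATURES, TIARA_FEATURE, encode_tiara, is_known_tiara_class
from .types import (
    ContigAnnotation,
    ContigFeatures,
    EUKARYOTE,
    GeneRecord,
    PROKARYOTE,
    TiaraPrediction,
    check_same_schema,
)

PathLike = Union[str, Path]


@dataclass
class ParseReport:
    """What a parser saw: record counts and collected warnings."""

    n_records: int = 0
    n_rejected: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)


@dataclass
class GFFParseResult:
    annotations: list[ContigAnnotation]
    report: ParseReport


_SEQLEN_RE = re.compile(r"seqlen=(\d+)")
_SEQHDR_RE = re.compile(r'seqhdr="([^"]*)"')


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col9.strip().strip(";").split(";"):
        if "=" in item:
            key, _, value = item.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def parse_prodigal_gff(path: PathLike) -> GFFParseResult:
    """Parse a Prodigal-style GFF3 file into per-contig annotations.

    Only CDS features are used; other feature types are skipped.  A gene
    has an RBS iff its ``rbs_motif`` attribute is present with a value
    other than the literal sentinel ``None``.  Contig lengths are taken
    from ``##sequence-region`` directives or Prodigal's
    ``# Sequence Data:`` comments when present; otherwise they stay unset
    and must be supplied via :func:`merge_lengths`.

    Records with end < start are rejected (counted in the report);
    non-integer coordinates raise :class:`GFFParseError` naming the line.
    """
    path = Path(path)
    report = ParseReport()
    genes: dict[str, list[GeneRecord]] = {}
    lengths: dict[str, int] = {}
    order: list[str] = []

    def note_contig(cid: str) -> None:
        if cid not in genes:
            genes[cid] = []
            order.append(cid)

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    note_contig(parts[1])
                    try:
                        lengths[parts[1]] = int(parts[3])
                    except ValueError:
                        report.warn(f"line {lineno}: bad sequence-region length")
                continue
            if line.startswith("#"):
                # Prodigal writes "# Sequence Data: seqnum=..;seqlen=..;seqhdr=".."
                mlen = _SEQLEN_RE.search(line)
                mhdr = _SEQHDR_RE.search(line)
                if mlen and mhdr:
                    cid = mhdr.group(1).split()[0] if mhdr.group(1) else ""
                    if cid:
                        note_contig(cid)
                        lengths[cid] = int(mlen.group(1))
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise GFFParseError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(cols)}"
                )
            contig_id, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols[:9]
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GFFParseError(
                    f"{path.name} line {lineno}: malformed coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if end < start:
                report.n_rejected += 1
                report.warn(f"line {lineno}: end {end} < start {start}; rejected")
                continue
            attrs = _parse_attributes(attr_s)
            has_rbs = attrs.get("rbs_motif", "None") != "None"
            note_contig(contig_id)
            genes[contig_id].append(
                GeneRecord(contig_id, start, end, strand, has_rbs)
            )
            report.n_records += 1

    annotations = []
    for cid in order:
        recs = sorted(genes[cid], key=lambda g: (g.start, g.end))
        recs = [
            GeneRecord(g.contig_id, g.start, g.end, g.strand, g.has_rbs, i)
            for i, g in enumerate(recs)
        ]
        annotations.append(
            ContigAnnotation(contig_id=cid, length=lengths.get(cid), genes=recs)
        )
    return GFFParseResult(annotations, report)


def read_prodigal_gff(path: PathLike) -> list[ContigAnnotation]:
    """As :func:`parse_prodigal_gff` but returning only the annotations."""
    return parse_prodigal_gff(path).annotations


def write_gff(annotations: Sequence[ContigAnnotation], path: PathLike) -> None:
    """Write annotations as Prodigal-style GFF3 (round-trips through
    :func:`read_prodigal_gff`, including contig lengths)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for seqnum, ann in enumerate(annotations, start=1):
            length = ann.length if ann.length is not None else 0
            fh.write(
                f'# Sequence Data: seqnum={seqnum};seqlen={length};'
                f'seqhdr="{ann.contig_id}"\n'
            )
            for i, g in enumerate(ann.genes, start=1):
                motif = "GGAGG" if g.has_rbs else "None"
                fh.write(
                    f"{ann.contig_id}\tkaryon\tCDS\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={seqnum}_{i};rbs_motif={motif};\n"
                )


def read_fasta_lengths(path: PathLike) -> dict[str, int]:
    """Map each FASTA record id (first header token) to its length in bp.

    Raises :class:`DuplicateIdError` listing any repeated ids.
    """
    lengths: dict[str, int] = {}
    duplicates: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            duplicates.append(rec.id)
        lengths[rec.id] = len(rec.seq)
    if duplicates:
        raise DuplicateIdError(f"duplicate FASTA ids: {sorted(set(duplicates))}")
    return lengths


def merge_lengths(
    annotations: Sequence[ContigAnnotation], lengths: Mapping[str, int]
) -> list[ContigAnnotation]:
    """Populate contig lengths from a FASTA-derived map.

    Every annotation id must be present in ``lengths``; a gene ending past
    the sequence length indicates a FASTA/GFF mismatch and raises
    :class:`CoordinateMismatchError`.
    """
    merged = []
    for ann in annotations:
        if ann.contig_id not in lengths:
            raise MissingLengthError(
                f"no sequence length known for contig {ann.contig_id!r}"
            )
        length = lengths[ann.contig_id]
        for g in ann.genes:
            if g.end > length:
                raise CoordinateMismatchError(
                    f"contig {ann.contig_id}: gene end {g.end} exceeds "
                    f"sequence length {length}"
                )
        merged.append(
            ContigAnnotation(
                contig_id=ann.contig_id,
                length=length,
                genes=list(ann.genes),
                label=ann.label,
                organism_id=ann.organism_id,
            )
        )
    return merged


@dataclass
class TiaraParseResult:
    predictions: list[TiaraPrediction]
    report: ParseReport


def parse_tiara_output(path: PathLike) -> TiaraParseResult:
    """Read a tab-separated table of external classifier calls.

    Accepts both a bare two-column (id, class) table and the tool's native
    multi-column layout; the class column is located by a header name
    containing "class" (falling back to column 2), the id column by a
    header containing "seq" or "id" (falling back to column 1).
    Unrecognized class strings are encoded as 2 with a warning.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    report = ParseReport()
    first = [str(v).lower() for v in raw.iloc[0]] if len(raw) else []
    has_header = any("class" in v for v in first)
    if has_header:
        header, body = list(raw.iloc[0]), raw.iloc[1:]
        lowered = [str(h).lower() for h in header]
        class_col = next(i for i, h in enumerate(lowered) if "class" in h)
        id_col = next(
            (i for i, h in enumerate(lowered) if "seq" in h or "id" in h), 0
        )
    else:
        body, class_col, id_col = raw, 1, 0

    predictions = []
    for _, row in body.iterrows():
        cid = str(row.iloc[id_col]).split()[0]
        cls = str(row.iloc[class_col]).strip()
        if not is_known_tiara_class(cls):
            report.warn(f"unrecognized class {cls!r} for {cid}; encoded as 2")
        predictions.append(TiaraPrediction(cid, cls, encode_tiara(cls)))
        report.n_records += 1
    return TiaraParseResult(predictions, report)


def read_tiara_output(path: PathLike) -> list[TiaraPrediction]:
    return parse_tiara_output(path).predictions


_TABLE_FLOAT_FORMAT = "%.12g"  # round-trips at 12 significant digits


def write_feature_table(
    rows: Union[Sequence[ContigFeatures], pd.DataFrame], path: PathLike
) -> None:
    """Write features as a TSV with a stable column order."""
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        if not check_same_schema(rows):
            raise SchemaError("feature rows disagree on presence of tiara_code")
        from .features import features_to_frame

        frame = features_to_frame(rows)
    frame.to_csv(path, sep="\t", float_format=_TABLE_FLOAT_FORMAT)


def read_feature_table(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="contig_id")
    expected = ["n_genes", *MODEL_FEATURES]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    if TIARA_FEATURE in frame.columns:
        frame[TIARA_FEATURE] = frame[TIARA_FEATURE].astype(int)
    return frame


def split_fasta_by_class(
    fasta_path: PathLike,
    predictions: Mapping[str, str],
    outdir: PathLike,
) -> dict[str, Path]:
    """Route FASTA records by predicted class.

    Eukaryote-classified records go to ``eukaryotes.fasta``, prokaryote-
    classified to ``prokaryotes.fasta``; ids absent from ``predictions``
    are listed in ``unclassified.txt``.  Input order is preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        EUKARYOTE: outdir / "eukaryotes.fasta",
        PROKARYOTE: outdir / "prokaryotes.fasta",
        "unclassified": outdir / "unclassified.txt",
    }
    with paths[EUKARYOTE].open("w") as euk, paths[PROKARYOTE].open("w") as prok, paths[
        "unclassified"
    ].open("w") as uncl:
        handles = {EUKARYOTE: euk, PROKARYOTE: prok}
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            cls = predictions.get(rec.id)
            if cls in handles:
                SeqIO.write(rec, handles[cls], "fasta")
            else:
                uncl.write(rec.id + "\n")
    return paths
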