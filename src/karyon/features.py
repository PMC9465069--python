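"""Gene-structure feature extraction.

Eukaryotic and prokaryotic genomes differ in how genes are laid out:
prokaryotic genes sit densely packed in co-oriented operons, often with
ribosome-binding-site (RBS) motifs, while (caller-predicted) eukaryotic
genes are sparser, shorter and less strand-coherent.  Eight per-contig
summaries of predicted gene coordinates capture this contrast:

* mean, standard deviation, first and third quartile of the intergenic
  distance (start of next gene − end of previous gene; negative when
  genes overlap),
* gene density (summed gene lengths / contig length),
* mean gene length (end − start),
* same-strand ratio (fraction of adjacent gene pairs sharing a strand),
* RBS ratio (fraction of genes with an RBS motif).

An optional ninth feature encodes an external k-mer classifier's call
(0 eukaryotic / 1 prokaryotic / 2 unknown-or-organelle).

Conventions fixed here so results are exactly reproducible: population
standard deviation (divide by n), linear-interpolation ("type 7")
quartiles, gene length computed as end − start with no +1.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InsufficientGenesError
from .types import ContigAnnotation, ContigFeatures, GeneRecord, TiaraPrediction

#: Model feature columns, in the frozen order used everywhere.
MODEL_FEATURES: tuple[str, ...] = (
    "ig_mean",
    "ig_std",
    "ig_q1",
    "ig_q3",
    "gene_density",
    "mean_gene_length",
    "same_strand_ratio",
    "rbs_ratio",
)
TIARA_FEATURE = "tiara_code"

#: Class string → three-level code. Matching is case-insensitive after trimming.
TIARA_ENCODING: dict[str, int] = {
    "eukarya": 0,
    "prokarya": 1,
    "bacteria": 1,
    "archaea": 1,
    "unknown": 2,
    "organelle": 2,
}
#: Code assigned to class strings outside the known vocabulary (and to
#: contigs with no prediction at all): the "unknown" bucket.
TIARA_UNKNOWN_CODE = 2


def encode_tiara(class_string: str) -> int:
    """Encode a k-mer classifier's class string as 0, 1 or 2.

    eukarya → 0; prokarya, bacteria, archaea → 1; unknown, organelle → 2.
    Any unrecognized string falls into the unknown bucket (2).
    """
    return TIARA_ENCODING.get(class_string.strip().lower(), TIARA_UNKNOWN_CODE)


def is_known_tiara_class(class_string: str) -> bool:
    return class_string.strip().lower() in TIARA_ENCODING


def intergenic_distances(genes: Sequence[GeneRecord]) -> list[int]:
    """Distances between consecutive genes: start(i+1) − end(i).

    Negative values (overlapping genes) are preserved.  Requires at least
    two genes.
    """
    if len(genes) < 2:
        raise InsufficientGenesError(
            f"need >= 2 genes to compute intergenic distances, got {len(genes)}"
        )
    return [genes[i + 1].start - genes[i].end for i in range(len(genes) - 1)]


def compute_contig_features(
    annotation: ContigAnnotation,
    tiara: Optional[TiaraPrediction] = None,
) -> ContigFeatures:
    """Compute the feature vector for one annotated contig.

    Raises :class:`InsufficientGenesError` for contigs with fewer than two
    predicted genes; callers are expected to exclude those contigs.
    """
    genes = annotation.genes
    if len(genes) < 2:
        raise InsufficientGenesError(
            f"contig {annotation.contig_id} has {len(genes)} gene(s); need >= 2"
        )
    if annotation.length is None or annotation.length <= 0:
        raise InsufficientGenesError(
            f"contig {annotation.contig_id} has no positive length"
        )

    ig = np.asarray(intergenic_distances(genes), dtype=float)
    lengths = np.asarray([g.length for g in genes], dtype=float)
    same_strand = sum(
        genes[i].strand == genes[i + 1].strand for i in range(len(genes) - 1)
    )
    n_pairs = len(genes) - 1
    n_rbs = sum(g.has_rbs for g in genes)

    return ContigFeatures(
        contig_id=annotation.contig_id,
        n_genes=len(genes),
        ig_mean=float(ig.mean()),
        ig_std=float(ig.std()),  # population form (ddof=0)
        ig_q1=float(np.percentile(ig, 25)),  # linear interpolation (type 7)
        ig_q3=float(np.percentile(ig, 75)),
        gene_density=float(lengths.sum() / annotation.length),
        mean_gene_length=float(lengths.mean()),
        same_strand_ratio=same_strand / n_pairs,
        rbs_ratio=n_rbs / len(genes),
        tiara_code=tiara.code if tiara is not None else None,
    )


def features_to_frame(
    rows: Sequence[ContigFeatures], use_tiara: Optional[bool] = None
) -> pd.DataFrame:
    """Assemble feature rows into a DataFrame indexed by contig id.

    Columns are ``n_genes`` followed by the model features in their frozen
    order (plus ``tiara_code`` when present).  ``n_genes`` is carried for
    reporting but is not a model feature.
    """
    if use_tiara is None:
        use_tiara = bool(rows) and rows[0].tiara_code is not None
    cols = ["n_genes", *MODEL_FEATURES] + ([TIARA_FEATURE] if use_tiara else [])
    data = {c: [getattr(r, c) for r in rows] for c in cols}
    index = pd.Index([r.contig_id for r in rows], name="contig_id")
    return pd.DataFrame(data, index=index, columns=cols)


class GeneStructureFeaturizer(TransformerMixin, BaseEstimator):
    """Transform contig annotations into the model feature matrix.

    Parameters
    ----------
    use_tiara : bool
        Append the encoded external prediction as a ninth feature column.
        Contigs without a prediction receive the "unknown" code 2.
    tiara : mapping of contig id → TiaraPrediction, optional
        Lookup table of external predictions; only consulted when
        ``use_tiara`` is true.

    After :meth:`transform`, ``excluded_ids_`` lists the contigs that were
    dropped for having fewer than two predicted genes.
    """

    def __init__(
        self,
        use_tiara: bool = False,
        tiara: Optional[Mapping[str, TiaraPrediction]] = None,
    ) -> None:
        self.use_tiara = use_tiara
        self.tiara = tiara

    def fit(self, X: Iterable[ContigAnnotation], y=None) -> "GeneStructureFeaturizer":
        # Stateless; present for scikit-learn API compatibility.
        return self

    def transform(self, X: Iterable[ContigAnnotation]) -> pd.DataFrame:
        tiara = self.tiara or {}
        rows: list[ContigFeatures] = []
        excluded: list[str] = []
        for ann in X:
            if ann.n_genes < 2:
                excluded.append(ann.contig_id)
                continue
            pred = tiara.get(ann.contig_id) if self.use_tiara else None
            if self.use_tiara and pred is None:
                pred = TiaraPrediction(ann.contig_id, "unknown", TIARA_UNKNOWN_CODE)
            rows.append(compute_contig_features(ann, pred))
        self.excluded_ids_ = excluded
        return features_to_frame(rows, use_tiara=self.use_tiara)

    def get_feature_names_out(self, input_features=None):
        cols = ["n_genes", *MODEL_FEATURES]
        if self.use_tiara:
            cols.append(TIARA_FEATURE)
        return np.asarray(cols, dtype=object)


def build_feature_matrix(
    annotations: Sequence[ContigAnnotation],
    tiara: Optional[Union[Mapping[str, TiaraPrediction], Sequence[TiaraPrediction]]] = None,
    use_tiara: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature matrix for many contigs, excluding those with < 2 genes.

    Returns the matrix (row order follows input order) and the list of
    excluded contig ids.
    """
    if tiara is not None and not isinstance(tiara, Mapping):
        tiara = {p.contig_id: p for p in tiara}
    fz = GeneStructureFeaturizer(use_tiara=use_tiara, tiara=tiara)
    frame = fz.fit_transform(annotations)
    return frame, fz.excluded_ids_


def model_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Drop bookkeeping columns, keeping only the model features."""
    keep = [c for c in frame.columns if c in MODEL_FEATURES or c == TIARA_FEATURE]
    return frame[keep]
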