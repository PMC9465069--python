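# Methods

## The classification model

A contig's class (eukaryote vs prokaryote) is predicted from the layout
of the genes a prokaryotic gene caller finds on it. The model is a
random forest of 100 trees with class weights inversely proportional to
class frequencies ("balanced"), unlimited depth and √p features per
split (ensemble-standard defaults, recorded in the model metadata). The
*standard* variant uses the eight gene-structure features; the
*with_tiara* variant appends the encoded call of an external k-mer
classifier as a ninth feature, letting the forest arbitrate between
structural and compositional evidence.

The approach assumes the gene caller was run in metagenomic mode on all
contigs, prokaryotic and eukaryotic alike. The signal is partly an
artefact of that choice — a prokaryotic caller fragments intron-bearing
genes into exon-sized pieces and finds spurious short "genes" in
intergenic eukaryotic sequence — but the artefact is systematic, which
is exactly what makes it discriminative.

## Feature conventions

All coordinates are GFF3: 1-based, fully inclusive, never converted.
Numerical conventions are fixed so that results are exactly
reproducible:

* intergenic distance dᵢ = start(gᵢ₊₁) − end(gᵢ), computed over the
  positionally ordered genes regardless of strand; negative values
  (overlapping genes, common in prokaryotes) are preserved, not clipped;
* standard deviation of the dᵢ in population form (divide by n);
* quartiles by linear interpolation between order statistics (the
  "type 7" convention, numpy's default);
* gene length = end − start, accepting the 1 bp undercount relative to
  biological length — the feature is used comparatively, so the constant
  offset is immaterial;
* a gene "has an RBS" iff the annotation carries an `rbs_motif`
  attribute with a value other than the literal sentinel `None`.

Contigs with fewer than two predicted genes have no intergenic distance
and are excluded from classification (they are reported with a reason
code instead). The gene count and contig length themselves are *not*
model features: both are strongly confounded with assembly quality and
fragment-length choice rather than taxon, so only their ratios enter.

The external-call encoding maps eukaryotic calls to 0; prokaryotic
calls (prokarya/bacteria/archaea) to 1; unknown and organelle to 2.
Matching is case-insensitive after trimming; unrecognized strings and
missing predictions fall into the unknown bucket (2), mirroring how the
external tool itself labels sequences it cannot place.

## Cross-validation

Model quality is estimated by stratified group k-fold (k = 5,
scikit-learn's `StratifiedGroupKFold`, shuffled with the run seed) with
the organism as the group: all contigs of one genome sit in exactly one
fold, preventing within-genome leakage, while class proportions are
approximately preserved across folds. Group integrity is asserted on
every run, not only in tests. Precision and recall are reported with
eukaryote as the positive class; the prokaryote-positive and macro
averages are carried alongside.

At a 50/50 vote-share tie the predicted class is prokaryote: downstream
prokaryote pipelines are the default consumers, and with 100 trees exact
ties are rare. The rule is documented and tested rather than left to
argmax ordering.

## Genome fragmentation

Training data is made by cutting reference assemblies into artificial
contigs. Records whose headers indicate non-nuclear DNA are dropped
first (keywords: mitochondrial, plastid, chloroplast, mitochondrion,
non-nuclear, organelle, apicoplast as case-insensitive substrings; the
short codes API and MIT only as standalone tokens, so "mitigated" or
"capital" never match). Each remaining sequence is tiled left to right
with lengths drawn from a triangular distribution on [5000, 100000] bp
with mode 10000 — the shape of contig lengths in typical metagenome
assemblies. The draw is taken before checking the remaining sequence;
when it exceeds what is left, the remainder is the terminal piece, kept
only if it reaches the 5000 bp lower limit, otherwise discarded (and
recorded, so length bookkeeping is exact). If a genome yields more than
500 fragments, a seeded uniform subsample of exactly 500 is kept —
sampling rather than truncation avoids positional bias toward chromosome
starts. Reference gene annotations are remapped onto fragments by
keeping genes fully contained in the window and shifting them to
fragment-relative coordinates; boundary-straddling genes are dropped.

## The synthetic data generator

The generator emulates *annotated* contigs — gene coordinate sets, not
nucleotide composition (any FASTA it writes holds uniform-random bases,
since sequence content never enters the model). Genes are laid down left
to right alternating a sampled intergenic gap (exponential with mean
`ig_mean_bp`; with probability `overlap_prob` replaced by a negative
overlap of at most 200 bp) and a sampled gene length (log-normal with
the given mean/SD, floored at 90 bp, the shortest ORF a caller
typically reports). Strand follows a two-state Markov chain with
persistence `strand_persistence` (operon co-orientation); RBS flags are
independent Bernoulli draws. At least two genes are guaranteed by
retrying with fresh draws and, if needed, progressively halving the gap
mean. Contig lengths come from the same triangular law as genome
fragmentation.

Class presets (fixture constants chosen once for qualitative realism,
not measurements of any real dataset):

| parameter | prokaryote | eukaryote |
|---|---|---|
| `ig_mean_bp` | 120 | 1500 |
| `gene_len_mean_bp` | 900 | 600 |
| `gene_len_sd_bp` | 300 | 350 |
| `strand_persistence` | 0.8 | 0.55 |
| `rbs_prob` | 0.7 | 0.3 |
| `overlap_prob` | 0.15 | 0.02 |

The eukaryote preset's short genes model a prokaryotic caller calling a
gene per exon. The gene-length SDs keep the coefficient of variation
near what annotated genomes show (~0.3–0.6). The default dataset is
10 organisms per class × 20 contigs; each synthetic organism draws its
own parameters by multiplicative log-normal jitter (default σ = 0.15,
roughly ±15% organism-to-organism spread) around its class preset, so
grouped cross-validation has genuinely distinct groups. A synthetic
stand-in for the external classifier's table flips each correct call to
the opposite class or "unknown" with a configurable error rate.

**What passing tests show — and don't.** The default presets separate
the classes strongly, so cross-validation on synthetic data reaching
~100% accuracy demonstrates that the pipeline recovers planted structure
through grouped CV without leakage; it says nothing about accuracy on
real metagenomes, where the class-conditional feature distributions
overlap far more (real-data estimates require the genome-download
recipe below). The generator also omits real-data features: assembly
chimerism, caller edge artefacts at contig ends, GC-dependent RBS
detection, and any correlation between gene structure and contig length.

## Numerical and degenerate-input choices

* Empty GFF → empty annotation list; empty FASTA → empty outputs with a
  warning and exit 0.
* End-before-start gene records are rejected with a counted warning;
  malformed coordinates abort with the line number.
* Feature tables round-trip at 12 significant digits; prediction tables
  print vote shares at 6 decimals (100 trees give steps of 0.01, so this
  is exact).
* Model files embed a schema version; a mismatch is a refusal, never a
  silent coercion. Tie-break and column order are part of the schema.
* Fragmentation of a sequence shorter than the lower length limit yields
  zero fragments (the whole sequence is a recorded discard).

## Problem sizes

Test and acceptance runs use the default synthetic conditions
(400 contigs, 20 organisms) for cross-validation, 100 000 draws for the
sampler check, 500 fuzzed annotations for the feature oracle and 20
fuzzed genomes for fragmentation bookkeeping; these sizes give stable
statistics while keeping the whole suite under a minute of compute.

## Known limitations

* Accuracy degrades on contigs under ~5 kb (few genes → noisy features);
  the classifier therefore defaults to a 5 kb minimum size and routes
  shorter contigs to the unclassified list.
* Organelle and viral contigs are not modelled as classes; organelle
  sequence is filtered from training data by header keywords only.
* The shipped package contains no pretrained model: training data
  depends on the gene caller version, so a model should be trained on
  fragments of reference genomes annotated with the same caller that
  will annotate the metagenome. The recipe: download reference
  assemblies (e.g. from NCBI), `karyon fragment` each, run the caller in
  metagenomic mode on the fragments, then `karyon train` with a manifest
  of per-organism GFFs.
* `vote_share` is the forest's vote fraction, not a calibrated
  probability.
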