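"""Independent naive recomputations used as oracles.

Everything here is written with plain Python loops and the `math`
module only, deliberately sharing no code path with the package, so a
disagreement always points at one side.
"""

from __future__ import annotations

import math
import random

from karyon.types import ContigAnnotation, GeneRecord


def naive_mean(xs):
    return sum(xs) / len(xs)


def naive_pop_std(xs):
    m = naive_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))


def naive_quantile_type7(xs, q):
    """Linear interpolation between order statistics."""
    s = sorted(xs)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    frac = h - lo
    if frac == 0:
        return float(s[lo])
    return s[lo] + frac * (s[lo + 1] - s[lo])


def naive_features(ann: ContigAnnotation) -> dict:
    genes = sorted(ann.genes, key=lambda g: (g.start, g.end))
    assert len(genes) >= 2
    ig = []
    for i in range(len(genes) - 1):
        ig.append(genes[i + 1].start - genes[i].end)
    lengths = [g.end - g.start for g in genes]
    same = 0
    for i in range(len(genes) - 1):
        if genes[i].strand == genes[i + 1].strand:
            same += 1
    return {
        "ig_mean": naive_mean(ig),
        "ig_std": naive_pop_std(ig),
        "ig_q1": naive_quantile_type7(ig, 0.25),
        "ig_q3": naive_quantile_type7(ig, 0.75),
        "gene_density": sum(lengths) / ann.length,
        "mean_gene_length": naive_mean(lengths),
        "same_strand_ratio": same / (len(genes) - 1),
        "rbs_ratio": sum(1 for g in genes if g.has_rbs) / len(genes),
    }


def fuzz_annotation(rnd: random.Random, contig_id: str = "fuzz") -> ContigAnnotation:
    """Random valid annotation: 2-30 genes, gaps in [-50, 3000] bp."""
    n = rnd.randint(2, 30)
    genes = []
    prev_start, prev_end = None, 0
    for i in range(n):
        gap = rnd.randint(-50, 3000)
        start = prev_end + gap
        if prev_start is not None:
            start = max(start, prev_start + 1)
        start = max(start, 1)
        length = rnd.randint(90, 2000)
        end = start + length
        genes.append(
            GeneRecord(
                contig_id=contig_id,
                start=start,
                end=end,
                strand=rnd.choice("+-"),
                has_rbs=rnd.random() < 0.5,
                gene_index=i,
            )
        )
        prev_start, prev_end = start, end
    length = genes[-1].end + rnd.randint(0, 5000)
    return ContigAnnotation(contig_id=contig_id, length=length, genes=genes)
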