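"""SNP-in-gene annotation.

A SNP is annotated with a gene iff its position lies within the gene's
span (1-based inclusive containment on the same seqid); no upstream or
downstream extension. Only GFF3 features of type "gene" are considered.
Strand never affects containment.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .types import GeneFeature, Locus


def _build_trees(gene_features: Iterable[GeneFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in gene_features:
        # intervaltree is half-open; +1 makes the gene end inclusive
        trees.setdefault(gene.seqid, IntervalTree()).addi(gene.start, gene.end + 1, gene)
    return trees


def genes_containing(locus: Locus, trees: dict[str, IntervalTree]) -> list[GeneFeature]:
    tree = trees.get(locus.chrom)
    if tree is None:
        return []
    hits = [iv.data for iv in tree.at(locus.pos)]
    return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))


def annotate_snps(loci: Sequence[Locus],
                  gene_features: Iterable[GeneFeature]) -> pd.DataFrame:
    """Annotate loci with the genes containing them.

    Returns a DataFrame with one row per (locus, containing gene); loci in
    no gene appear once with empty gene fields, loci in overlapping genes
    yield multiple rows.
    """
    trees = _build_trees(gene_features)
    rows = []
    for locus in loci:
        hits = genes_containing(locus, trees)
        if not hits:
            rows.append((locus.chrom, locus.pos, locus.ref, locus.alt, "", ""))
        for gene in hits:
            rows.append((locus.chrom, locus.pos, locus.ref, locus.alt,
                         gene.gene_id, gene.gene_name))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "gene_id", "gene_name"])


def write_annotation(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
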