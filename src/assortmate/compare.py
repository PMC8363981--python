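"""Cross-group comparison of per-locus assortment classifications.

Given the per-locus results of two mating categories (e.g., natural-origin
pairs vs. hatchery-origin pairs), counts how many flagged SNPs the groups
share in each direction. The shared percentage uses the *sum* of the two
groups' flagged counts as denominator, i.e. pct = 100 * shared / (n_a +
n_b) — an unconventional choice (the union would be more common) kept
because it is the convention the counts are reported under.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .types import Classification, LocusAssortResult


def _round2(x: float) -> float:
    """Round half-up to 2 decimal places (table formatting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def shared_percentage(shared: int, n_a: int, n_b: int) -> float:
    """100 * shared / (n_a + n_b), rounded half-up to 2 dp; 0 if both empty."""
    total = n_a + n_b
    return _round2(100.0 * shared / total) if total else 0.0


@dataclass
class GroupComparison:
    group_a_label: str
    group_b_label: str
    n_negative_a: int
    n_negative_b: int
    n_positive_a: int
    n_positive_b: int
    shared_negative: int
    shared_positive: int
    pct_shared_negative: float
    pct_shared_positive: float
    same_direction: int
    opposite_direction: int
    per_chromosome_counts: dict = field(default_factory=dict)  # chrom -> (neg_a, pos_a, neg_b, pos_b)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def _class_map(results: list[LocusAssortResult], side: str) -> dict:
    out = {}
    for r in results:
        if r.locus in out:
            raise ValueError(f"duplicate locus {r.locus.key} in results {side}")
        out[r.locus] = r.classification
    return out


def compare_groups(results_a: list[LocusAssortResult],
                   results_b: list[LocusAssortResult],
                   group_a_label: str = "a",
                   group_b_label: str = "b") -> GroupComparison:
    """Compare two groups' classifications over the union of their loci.

    Loci absent from one side count as classification 'none' there.
    same_direction = loci flagged with the same sign in both groups
    (= shared_negative + shared_positive); opposite_direction = loci
    flagged in both groups with differing signs.
    """
    a = _class_map(results_a, group_a_label)
    b = _class_map(results_b, group_b_label)

    n_neg_a = sum(1 for c in a.values() if c is Classification.negative)
    n_pos_a = sum(1 for c in a.values() if c is Classification.positive)
    n_neg_b = sum(1 for c in b.values() if c is Classification.negative)
    n_pos_b = sum(1 for c in b.values() if c is Classification.positive)

    shared_neg = shared_pos = opposite = 0
    per_chrom: dict[str, list[int]] = {}
    for locus in set(a) | set(b):
        ca = a.get(locus, Classification.none)
        cb = b.get(locus, Classification.none)
        counts = per_chrom.setdefault(locus.chrom, [0, 0, 0, 0])
        if ca is Classification.negative:
            counts[0] += 1
        elif ca is Classification.positive:
            counts[1] += 1
        if cb is Classification.negative:
            counts[2] += 1
        elif cb is Classification.positive:
            counts[3] += 1
        if ca is Classification.none or cb is Classification.none:
            continue
        if ca is cb:
            if ca is Classification.negative:
                shared_neg += 1
            else:
                shared_pos += 1
        else:
            opposite += 1

    return GroupComparison(
        group_a_label=group_a_label,
        group_b_label=group_b_label,
        n_negative_a=n_neg_a,
        n_negative_b=n_neg_b,
        n_positive_a=n_pos_a,
        n_positive_b=n_pos_b,
        shared_negative=shared_neg,
        shared_positive=shared_pos,
        pct_shared_negative=shared_percentage(shared_neg, n_neg_a, n_neg_b),
        pct_shared_positive=shared_percentage(shared_pos, n_pos_a, n_pos_b),
        same_direction=shared_neg + shared_pos,
        opposite_direction=opposite,
        per_chromosome_counts={c: tuple(v) for c, v in sorted(per_chrom.items())},
    )


def summarize_by_chromosome(results: list[LocusAssortResult],
                            chromosomes: Optional[set] = None) -> dict[str, tuple[int, int]]:
    """Counts of (negative, positive) flagged loci per chromosome.

    When ``chromosomes`` is given, seqids outside it (unanchored scaffolds)
    collapse into an "unplaced" bucket.
    """
    out: dict[str, list[int]] = {}
    for r in results:
        if r.classification is Classification.none:
            continue
        chrom = r.locus.chrom
        if chromosomes is not None and chrom not in chromosomes:
            chrom = "unplaced"
        counts = out.setdefault(chrom, [0, 0])
        if r.classification is Classification.negative:
            counts[0] += 1
        else:
            counts[1] += 1
    return {c: (v[0], v[1]) for c, v in sorted(out.items())}


def write_per_chromosome_tsv(comparison: GroupComparison, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tnegative_a\tpositive_a\tnegative_b\tpositive_b\n")
        for chrom, (na, pa, nb, pb) in comparison.per_chromosome_counts.items():
            fh.write(f"{chrom}\t{na}\t{pa}\t{nb}\t{pb}\n")


def plot_comparison(comparison: GroupComparison, path) -> None:
    """Per-chromosome bar chart of flagged-SNP counts for both groups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    chroms = list(comparison.per_chromosome_counts)
    data = np.array([comparison.per_chromosome_counts[c] for c in chroms]) \
        if chroms else np.zeros((0, 4))
    x = np.arange(len(chroms))
    fig, axes = plt.subplots(2, 1, figsize=(max(6, 0.35 * len(chroms)), 6), sharex=True)
    for ax, (neg_col, pos_col, label) in zip(
            axes, [(0, 1, comparison.group_a_label), (2, 3, comparison.group_b_label)]):
        if len(chroms):
            ax.bar(x - 0.2, data[:, neg_col], width=0.4, label="negative")
            ax.bar(x + 0.2, data[:, pos_col], width=0.4, label="positive")
        ax.set_ylabel(f"{label}: flagged SNPs")
        ax.legend()
    axes[1].set_xticks(x)
    axes[1].set_xticklabels(chroms, rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
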