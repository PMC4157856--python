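"""Reference tag index for NlaIII-anchored digital gene expression.

In DGE tag profiling each transcript is represented by short sequence tags
anchored at CATG (NlaIII) restriction sites: the 17 bases immediately 3' of
a CATG are one *reference tag*. A gene usually carries several CATG sites and
therefore several reference tags; the tag from the 3'-most site is the
*canonical* tag that the library-preparation chemistry actually sequences.
A reference tag shared verbatim by more than one gene is *ambiguous* and
cannot be used for unambiguous quantification.

This module builds the tag index from gene sequences and produces the
standard reference accounting (genes with a CATG site, total / unambiguous /
ambiguous reference tags, with percentages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

TAG_LENGTH = 17
ANCHOR = "CATG"

__all__ = [
    "TAG_LENGTH",
    "ANCHOR",
    "GeneRecord",
    "TagLibraryIndex",
    "extract_reference_tags",
    "reference_summary",
    "summary_from_counts",
    "InputError",
]


class InputError(ValueError):
    """Raised for malformed inputs (duplicate ids, empty record sets, ...)."""


_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GeneRecord:
    """A reference gene: identifier, sequence, and annotation terms."""

    gene_id: str
    sequence: str
    terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"gene {self.gene_id!r}: empty sequence")
        if not set(self.sequence) <= _ALPHABET:
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise InputError(
                f"gene {self.gene_id!r}: sequence contains non-ACGTN characters {bad}"
            )


def _qualifying_tags(sequence: str):
    """Yield (position, tag) for every CATG site followed by >=17 bases.

    A tag window containing 'N' is disqualified: it could never be matched
    under the perfect/1-mismatch rule.
    """
    start = 0
    while True:
        i = sequence.find(ANCHOR, start)
        if i < 0:
            return
        tag = sequence[i + 4 : i + 4 + TAG_LENGTH]
        if len(tag) == TAG_LENGTH and "N" not in tag:
            yield i, tag
        start = i + 1


@dataclass
class TagLibraryIndex:
    """Mapping from 17 bp reference tags to the genes they derive from.

    Attributes
    ----------
    tag_to_genes
        Every reference tag -> sorted tuple of gene ids carrying it.
    canonical_tag
        Gene id -> tag at its 3'-most qualifying CATG site (the tag the DGE
        chemistry sequences for that transcript).
    n_genes, n_genes_with_catg
        Reference accounting: total genes, and genes with at least one
        qualifying CATG site (site followed by a full N-free 17 bp window).
    """

    tag_to_genes: Mapping[str, tuple]
    canonical_tag: Mapping[str, str]
    n_genes: int
    n_genes_with_catg: int

    @property
    def n_tags(self) -> int:
        return len(self.tag_to_genes)

    @property
    def n_unambiguous(self) -> int:
        return sum(1 for g in self.tag_to_genes.values() if len(g) == 1)

    @property
    def n_ambiguous(self) -> int:
        return self.n_tags - self.n_unambiguous

    def is_ambiguous(self, tag: str) -> bool:
        return len(self.tag_to_genes[tag]) > 1


def extract_reference_tags(genes: Iterable[GeneRecord]) -> TagLibraryIndex:
    """Build the reference tag index from gene sequences.

    Every occurrence of CATG followed by at least 17 bases contributes the 17
    bases 3' of the site as a reference tag for that gene.  Genes lacking any
    qualifying site are counted in the totals but contribute no tags.

    Raises
    ------
    InputError
        On an empty gene list or duplicate gene ids.
    """
    genes = list(genes)
    if not genes:
        raise InputError("empty reference: no gene records")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise InputError(f"duplicate gene ids: {sorted(dups)[:5]}")

    tag_to_genes: dict[str, set] = {}
    canonical: dict[str, str] = {}
    n_with_catg = 0
    for gene in genes:
        sites = list(_qualifying_tags(gene.sequence))
        if not sites:
            continue
        n_with_catg += 1
        for _, tag in sites:
            tag_to_genes.setdefault(tag, set()).add(gene.gene_id)
        canonical[gene.gene_id] = sites[-1][1]  # 3'-most site

    frozen = {t: tuple(sorted(g)) for t, g in tag_to_genes.items()}
    return TagLibraryIndex(
        tag_to_genes=frozen,
        canonical_tag=canonical,
        n_genes=len(genes),
        n_genes_with_catg=n_with_catg,
    )


def summary_from_counts(
    n_genes: int, n_genes_with_catg: int, n_unambiguous: int, n_ambiguous: int
) -> pd.DataFrame:
    """Reference accounting table from raw counts.

    Percentages use the gene total for the gene row and the tag total for tag
    rows, rounded to two decimals.  An empty tag set reports 0% throughout.
    """
    n_tags = n_unambiguous + n_ambiguous

    def pct(count, denom):
        return round(count / denom * 100, 2) if denom else 0.0

    rows = [
        ("Reference genes", n_genes, None),
        ("Genes with CATG site", n_genes_with_catg, pct(n_genes_with_catg, n_genes)),
        ("Total reference tags", n_tags, None),
        ("Unambiguous tags", n_unambiguous, pct(n_unambiguous, n_tags)),
        ("Ambiguous tags", n_ambiguous, pct(n_ambiguous, n_tags)),
    ]
    frame = pd.DataFrame(rows, columns=["category", "count", "percentage"])
    frame.attrs["strand_policy"] = "sense strand only, 17 bases 3' of CATG"
    return frame


def reference_summary(index: TagLibraryIndex) -> pd.DataFrame:
    """Reference accounting (gene/tag counts and percentages) for an index."""
    return summary_from_counts(
        index.n_genes, index.n_genes_with_catg, index.n_unambiguous, index.n_ambiguous
    )
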