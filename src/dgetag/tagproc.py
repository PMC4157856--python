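"""Clean, filter and map sequenced DGE tags to the reference index.

The processing chain mirrors standard tag-profiling practice:

raw tags -> ``clean_tags``       (drop adaptor and ambiguous-base tags)
         -> ``drop_singletons``  (keep tags with more than one copy)
         -> ``map_tags``         (perfect or 1-mismatch match to the index)
         -> ``compute_tpm``      (transcripts per million clean tags)

``saturation_curve`` subsamples a raw tag stream at increasing depths and
records how many genes are detected, the standard check that sequencing depth
suffices for transcriptome coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .reference import TAG_LENGTH, TagLibraryIndex, InputError

__all__ = [
    "TagCountTable",
    "LibraryExpression",
    "ExpressionTable",
    "MappingReport",
    "clean_tags",
    "drop_singletons",
    "map_tags",
    "combine_libraries",
    "compute_tpm",
    "saturation_curve",
]

_STAGES = ("raw", "clean", "analysis")


@dataclass
class TagCountTable:
    """Distinct tag -> count table for one library at one processing stage."""

    library_id: str
    frame: pd.DataFrame  # columns: tag, count
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise InputError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        if list(self.frame.columns[:2]) != ["tag", "count"]:
            raise InputError("tag table must have columns ('tag', 'count')")
        if self.frame["tag"].duplicated().any():
            raise InputError("tags must be distinct within a table")
        if (self.frame["count"] < 0).any():
            raise InputError("tag counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.frame["count"].sum())

    @property
    def n_distinct(self) -> int:
        return len(self.frame)

    @classmethod
    def from_counts(cls, library_id: str, counts: dict, stage: str = "raw"):
        frame = pd.DataFrame(
            {"tag": list(counts.keys()), "count": list(counts.values())}
        )
        return cls(library_id=library_id, frame=frame, stage=stage)


def clean_tags(
    raw: TagCountTable, adaptor: str, prefix_length: Optional[int] = None
) -> TagCountTable:
    """Remove adaptor-contaminated and ambiguous-base tags.

    A tag is removed if it contains any non-ACGT character, or if its sequence
    begins with the first ``prefix_length`` bases of ``adaptor`` (default: the
    whole adaptor, truncated to tag length).
    """
    if raw.stage != "raw":
        raise InputError(f"clean_tags expects a raw-stage table, got {raw.stage!r}")
    plen = min(prefix_length or len(adaptor), TAG_LENGTH, len(adaptor))
    prefix = adaptor[:plen]
    tags = raw.frame["tag"]
    ok = tags.str.fullmatch("[ACGT]+") & ~tags.str.startswith(prefix)
    frame = raw.frame.loc[ok].reset_index(drop=True)
    return TagCountTable(library_id=raw.library_id, frame=frame, stage="clean")


def drop_singletons(clean: TagCountTable) -> TagCountTable:
    """Keep only tags with more than one copy (robustness filter)."""
    if clean.stage != "clean":
        raise InputError(
            f"drop_singletons expects a clean-stage table, got {clean.stage!r}"
        )
    frame = clean.frame.loc[clean.frame["count"] > 1].reset_index(drop=True)
    return TagCountTable(library_id=clean.library_id, frame=frame, stage="analysis")


@dataclass
class MappingReport:
    """Library-level tag-to-gene mapping accounting.

    ``totals`` count tag copies; ``distinct`` count distinct tag sequences.
    Conservation: mapped + genome + unknown = input clean total, in both
    views.
    """

    library_id: str
    total_clean: int
    distinct_clean: int
    total_mapped: int
    distinct_mapped: int
    total_unambiguous: int
    distinct_unambiguous: int
    total_genome: int
    distinct_genome: int
    total_unknown: int
    distinct_unknown: int
    genes_all: int
    genes_unambiguous: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Clean tags", self.total_clean, self.distinct_clean),
            ("All tags mapping to genes", self.total_mapped, self.distinct_mapped),
            (
                "Unambiguous tag mapping to genes",
                self.total_unambiguous,
                self.distinct_unambiguous,
            ),
            ("All tag-mapped genes", self.genes_all, self.genes_all),
            ("Unambiguous tag-mapped genes", self.genes_unambiguous, self.genes_unambiguous),
            ("Mapping to genome", self.total_genome, self.distinct_genome),
            ("Unknown tags", self.total_unknown, self.distinct_unknown),
        ]
        return pd.DataFrame(rows, columns=["category", "total", "distinct"])


@dataclass
class LibraryExpression:
    """Per-gene tag counts for one library.

    ``count`` holds unambiguously assigned copies (the analysis-grade
    quantity); ``all_count`` credits ambiguous tags to every candidate gene
    and is used for detection/saturation accounting only.
    """

    library_id: str
    frame: pd.DataFrame  # index: gene, columns: count, all_count [, tpm]
    clean_total: int


@dataclass
class ExpressionTable:
    """Two-library per-gene counts ready for differential testing."""

    frame: pd.DataFrame  # index gene; columns x, y [, tpm1, tpm2]
    n1: int
    n2: int
    library_ids: tuple = ("library1", "library2")


_BASES = "ACGT"


def _one_mismatch_variants(tag: str):
    for i, base in enumerate(tag):
        left, right = tag[:i], tag[i + 1 :]
        for b in _BASES:
            if b != base:
                yield left + b + right


def classify_tag(tag: str, index: TagLibraryIndex):
    """Resolve one tag against the index under the perfect/1-mismatch rule.

    Returns the sorted tuple of candidate gene ids (empty if no reference tag
    lies within Hamming distance 1).  An exact hit takes absolute precedence;
    otherwise candidates are the union of genes over all distance-1 reference
    tags.
    """
    hit = index.tag_to_genes.get(tag)
    if hit is not None:
        return hit
    genes: set = set()
    for variant in _one_mismatch_variants(tag):
        g = index.tag_to_genes.get(variant)
        if g is not None:
            genes.update(g)
    return tuple(sorted(genes))


def map_tags(
    analysis: TagCountTable,
    index: TagLibraryIndex,
    clean_total: Optional[int] = None,
    decoy_tags: Optional[set] = None,
) -> tuple[LibraryExpression, MappingReport]:
    """Map an analysis-stage tag table to genes.

    Each tag is looked up exactly, then (failing that) against all 51
    single-base variants.  Tags resolving to exactly one gene contribute
    unambiguous counts; tags resolving to several genes are mapped-but-
    ambiguous; tags matching the optional genome decoy set fall into the
    genome bucket; everything else is unknown.

    ``clean_total`` is the library's clean-tag total used later as the TPM
    denominator (defaults to the table's own total).
    """
    if analysis.stage != "analysis":
        raise InputError(
            f"map_tags expects an analysis-stage table, got {analysis.stage!r}"
        )
    if index.n_tags == 0:
        raise InputError("empty reference index")
    bad = ~analysis.frame["tag"].str.fullmatch("[ACGT]+")
    if bad.any():
        example = analysis.frame.loc[bad, "tag"].iloc[0]
        raise InputError(f"non-ACGT tag in analysis table: {example!r}")

    unamb: dict[str, int] = {}
    all_counts: dict[str, int] = {}
    genes_all: set = set()
    t_map = d_map = t_un = d_un = t_gen = d_gen = t_unk = d_unk = 0

    for tag, count in zip(analysis.frame["tag"], analysis.frame["count"]):
        count = int(count)
        genes = classify_tag(tag, index)
        if genes:
            t_map += count
            d_map += 1
            genes_all.update(genes)
            for g in genes:
                all_counts[g] = all_counts.get(g, 0) + count
            if len(genes) == 1:
                t_un += count
                d_un += 1
                g = genes[0]
                unamb[g] = unamb.get(g, 0) + count
        elif decoy_tags is not None and _hits_decoy(tag, decoy_tags):
            t_gen += count
            d_gen += 1
        else:
            t_unk += count
            d_unk += 1

    frame = pd.DataFrame(
        {
            "count": pd.Series(unamb, dtype="int64"),
            "all_count": pd.Series(all_counts, dtype="int64"),
        }
    ).fillna(0).astype("int64")
    frame.index.name = "gene"
    frame = frame.sort_index()

    expr = LibraryExpression(
        library_id=analysis.library_id,
        frame=frame,
        clean_total=int(clean_total) if clean_total is not None else analysis.total,
    )
    report = MappingReport(
        library_id=analysis.library_id,
        total_clean=analysis.total,
        distinct_clean=analysis.n_distinct,
        total_mapped=t_map,
        distinct_mapped=d_map,
        total_unambiguous=t_un,
        distinct_unambiguous=d_un,
        total_genome=t_gen,
        distinct_genome=d_gen,
        total_unknown=t_unk,
        distinct_unknown=d_unk,
        genes_all=len(genes_all),
        genes_unambiguous=len(unamb),
    )
    return expr, report


def _hits_decoy(tag: str, decoy: set) -> bool:
    if tag in decoy:
        return True
    return any(v in decoy for v in _one_mismatch_variants(tag))


def compute_tpm(expr: LibraryExpression) -> LibraryExpression:
    """Add a TPM column: count / clean_total x 1e6, on unambiguous counts."""
    if expr.clean_total <= 0:
        raise InputError("clean-tag total must be positive for TPM")
    frame = expr.frame.copy()
    frame["tpm"] = frame["count"] / expr.clean_total * 1e6
    return replace(expr, frame=frame)


def combine_libraries(
    lib1: LibraryExpression, lib2: LibraryExpression
) -> ExpressionTable:
    """Outer-join two libraries into an x/y count table with TPM columns."""
    merged = pd.DataFrame(
        {
            "x": lib1.frame["count"],
            "y": lib2.frame["count"],
        }
    ).fillna(0).astype("int64")
    merged.index.name = "gene"
    merged["tpm1"] = merged["x"] / lib1.clean_total * 1e6
    merged["tpm2"] = merged["y"] / lib2.clean_total * 1e6
    return ExpressionTable(
        frame=merged.sort_index(),
        n1=lib1.clean_total,
        n2=lib2.clean_total,
        library_ids=(lib1.library_id, lib2.library_id),
    )


def saturation_curve(
    raw_tag_stream: Sequence[str],
    index: TagLibraryIndex,
    grid: Iterable[int],
    seed: int,
    adaptor: str = "",
) -> pd.DataFrame:
    """Detected genes as a function of sequencing depth.

    The raw per-copy tag stream is shuffled once (``seed``); each grid point
    takes the corresponding prefix, i.e. nested subsamples drawn without
    replacement, so both detection columns are non-decreasing by
    construction.  Tags are cleaned (adaptor/N filter) and mapped under the
    perfect/1-mismatch rule; a gene counts as detected when any mapped tag
    (ambiguous included) hits it, and as unambiguously detected when a
    uniquely-resolving tag hits it.
    """
    grid = [int(g) for g in grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise InputError("subsample grid must be strictly increasing")
    stream = np.asarray(raw_tag_stream, dtype=object)
    if grid and grid[-1] > len(stream):
        raise InputError(
            f"grid point {grid[-1]} exceeds stream length {len(stream)}"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stream))
    stream = stream[order]

    # Classify each distinct tag once; prefixes then only merge gene sets.
    codes, uniques = pd.factorize(stream)
    plen = min(len(adaptor), TAG_LENGTH) if adaptor else 0
    tag_genes = []
    tag_unamb = []
    for tag in uniques:
        if (set(tag) - set("ACGT")) or (plen and tag.startswith(adaptor[:plen])):
            tag_genes.append(())
            tag_unamb.append(None)
            continue
        genes = classify_tag(tag, index)
        tag_genes.append(genes)
        tag_unamb.append(genes[0] if len(genes) == 1 else None)

    detected_all: set = set()
    detected_un: set = set()
    seen = np.zeros(len(uniques), dtype=bool)
    rows = []
    prev = 0
    for g in grid:
        segment = codes[prev:g]
        for code in np.unique(segment):
            if not seen[code]:
                seen[code] = True
                detected_all.update(tag_genes[code])
                u = tag_unamb[code]
                if u is not None:
                    detected_un.add(u)
        rows.append((g, len(detected_all), len(detected_un)))
        prev = g
    return pd.DataFrame(
        rows, columns=["tags_sampled", "genes_all", "genes_unambiguous"]
    )
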