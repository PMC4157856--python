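"""Synthetic DGE study generator with known ground truth.

Emulates a two-condition tag-profiling experiment end to end: a reference
transcriptome in which most genes carry at least one CATG site, gene-to-term
annotation tables, and two raw tag libraries sampled from a heavy-tailed
(log-normal) abundance distribution with a configurable minority of
differentially expressed genes.  Raw libraries are corrupted the way real
sequencing corrupts them: per-base substitution errors on sampled copies
(producing 1-mismatch tags), injected adaptor reads, ambiguous-base ('N')
reads, and reads from sequence absent from the reference ("unknown tags").

Because the truth (per-gene abundances, injected log2 effects, DE gene set)
is recorded, every downstream stage — cleaning, mapping, TPM, differential
testing, enrichment — can be validated quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .reference import GeneRecord, TAG_LENGTH, extract_reference_tags
from .tagproc import TagCountTable

__all__ = [
    "ADAPTOR",
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "GenerationError",
    "simulate_reference",
    "simulate_annotations",
    "make_ground_truth",
    "simulate_tag_libraries",
    "tag_stream",
    "simulate_study",
]

# Fixed synthetic adaptor 17-mer used for contamination injection and the
# default cleaning prefix.  Contains no CATG.
ADAPTOR = "GATCGGAAGAGCTCGTA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


class GenerationError(RuntimeError):
    """Simulation cannot proceed (e.g. expressed gene without a CATG site)."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic two-library DGE study.

    Defaults describe the emulated study: a reference of 10,000 genes with
    92.28% carrying a CATG site, two libraries of 2 million raw tags, 5% of
    expressed genes differentially expressed at |log2 fold| = 2 (restricted
    to genes of at least 50 true TPM), per-base error 0.001, and raw-tag
    contamination fractions taken from typical library accounting
    (adaptor 1.5%, ambiguous-base 1.2%, non-reference 25%).
    """

    n_genes: int = 10_000
    frac_catg: float = 0.9228
    gene_length_range: tuple = (200, 4000)
    n1: int = 2_000_000
    n2: int = 2_000_000
    frac_de: float = 0.05
    log2_effects: tuple = (2.0,)
    de_min_tpm: float = 50.0
    lognormal_mean: float = 0.0
    lognormal_sigma: float = 1.5
    per_base_error: float = 0.001
    frac_adaptor: float = 0.015
    frac_ambiguous_base: float = 0.012
    frac_unknown: float = 0.25
    n_terms: int = 50
    term_size_range: tuple = (10, 200)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        for name in ("frac_catg", "frac_de", "per_base_error", "frac_adaptor",
                     "frac_ambiguous_base", "frac_unknown"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_adaptor + self.frac_ambiguous_base + self.frac_unknown > 1:
            raise ConfigError(
                "frac_adaptor + frac_ambiguous_base + frac_unknown exceeds 1"
            )
        if self.n1 <= 0 or self.n2 <= 0:
            raise ConfigError("n1 and n2 must be positive")
        lo, hi = self.gene_length_range
        if lo < TAG_LENGTH + 4:
            raise ConfigError(
                f"gene_length_range minimum must be >= {TAG_LENGTH + 4} bp "
                "(room for CATG plus a full tag)"
            )
        if hi < lo:
            raise ConfigError("gene_length_range must be (low, high) with low <= high")
        if self.n_terms < 0:
            raise ConfigError("n_terms must be non-negative")
        tlo, thi = self.term_size_range
        if tlo < 1 or thi < tlo:
            raise ConfigError("term_size_range must be (low, high) with 1 <= low <= high")
        if self.lognormal_sigma <= 0:
            raise ConfigError("lognormal_sigma must be positive")
        if self.de_min_tpm < 0:
            raise ConfigError("de_min_tpm must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """True per-gene abundances, injected effects, and annotations.

    ``frame`` is indexed by gene id with columns ``abundance1``,
    ``abundance2`` (each summing to 1 over expressed genes) and
    ``log2_effect`` (exactly 0 for non-DE genes).
    """

    frame: pd.DataFrame
    de_genes: frozenset
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def true_tpm1(self) -> pd.Series:
        return self.frame["abundance1"] * 1e6

    @property
    def true_tpm2(self) -> pd.Series:
        return self.frame["abundance2"] * 1e6


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # Independent per-stage streams all keyed off the one root seed.
    return np.random.default_rng([config.seed, stream])


def _random_sequences(rng, lengths):
    total = int(np.sum(lengths))
    codes = rng.integers(0, 4, size=total, dtype=np.uint8)
    chars = _BASES[codes].tobytes().decode("ascii")
    out, pos = [], 0
    for L in lengths:
        out.append(chars[pos : pos + int(L)])
        pos += int(L)
    return out


def _has_qualifying_catg(seq: str) -> bool:
    i = seq.find("CATG")
    while i >= 0:
        if len(seq) - (i + 4) >= TAG_LENGTH and "N" not in seq[i + 4 : i + 4 + TAG_LENGTH]:
            return True
        i = seq.find("CATG", i + 1)
    return False


def _scrub_catg(seq: str, rng) -> str:
    """Destroy every CATG occurrence by mutating one of its bases."""
    while True:
        i = seq.find("CATG")
        if i < 0:
            return seq
        j = i + int(rng.integers(4))
        old = seq[j]
        new = "ACGT"[(("ACGT".index(old)) + int(rng.integers(1, 4))) % 4]
        seq = seq[:j] + new + seq[j + 1 :]


def simulate_reference(config: SimConfig) -> list:
    """Generate ``n_genes`` random gene sequences.

    Each gene independently (probability ``frac_catg``) is guaranteed at
    least one qualifying CATG site (CATG followed by a full 17 bp window);
    the remaining genes are scrubbed of CATG entirely, so the realized
    CATG-bearing count is Binomial(n_genes, frac_catg).
    """
    rng = _rng(config, 0)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    seqs = _random_sequences(rng, lengths)
    with_catg = rng.random(config.n_genes) < config.frac_catg

    width = len(str(config.n_genes))
    genes = []
    for i, seq in enumerate(seqs):
        if with_catg[i]:
            if not _has_qualifying_catg(seq):
                pos = int(rng.integers(0, len(seq) - TAG_LENGTH - 3))
                seq = seq[:pos] + "CATG" + seq[pos + 4 :]
        else:
            seq = _scrub_catg(seq, rng)
        genes.append(GeneRecord(gene_id=f"G{i:0{width}d}", sequence=seq))
    return genes


def simulate_annotations(genes: Sequence[GeneRecord], config: SimConfig) -> pd.DataFrame:
    """Random gene-to-term assignments.

    Produces ``n_terms`` terms with membership sizes uniform over
    ``term_size_range``; the first half are labelled as GO terms, the rest as
    pathways (the enrichment mathematics treats both identically).
    """
    if not genes:
        raise ConfigError("genes must be non-empty for annotation simulation")
    if config.term_size_range[1] > len(genes):
        raise ConfigError(
            f"term_size_range maximum {config.term_size_range[1]} exceeds "
            f"n_genes={len(genes)}"
        )
    rng = _rng(config, 1)
    ids = np.array([g.gene_id for g in genes])
    rows = []
    n_go = (config.n_terms + 1) // 2
    for t in range(config.n_terms):
        size = int(rng.integers(config.term_size_range[0], config.term_size_range[1] + 1))
        members = rng.choice(ids, size=size, replace=False)
        if t < n_go:
            term, namespace = f"GO:{t:07d}", "GO"
        else:
            term, namespace = f"ko{t:05d}", "KEGG"
        for g in sorted(members):
            rows.append((g, term, namespace))
    return pd.DataFrame(rows, columns=["gene", "term", "namespace"])


def make_ground_truth(
    genes: Sequence[GeneRecord],
    config: SimConfig,
    annotations: Optional[pd.DataFrame] = None,
) -> GroundTruth:
    """Draw true abundances and inject differential expression.

    Expressed genes are exactly those with a qualifying CATG site (they have
    a canonical tag to be sequenced).  Base abundances are log-normal,
    normalized to sum 1; this baseline is library 2 ("normal").  A fraction
    ``frac_de`` of expressed genes — restricted to genes whose true TPM is at
    least ``de_min_tpm`` — get a log2 effect applied in library 1
    ("deformed"), symmetric up/down when ``log2_effects`` lists magnitudes
    only; library 1 is then renormalized.
    """
    rng = _rng(config, 2)
    index = extract_reference_tags(genes)
    expressed = sorted(index.canonical_tag)
    if not expressed:
        raise GenerationError("no gene carries a qualifying CATG site")

    n_expr = len(expressed)
    a2 = rng.lognormal(config.lognormal_mean, config.lognormal_sigma, n_expr)
    a2 = a2 / a2.sum()

    eligible = np.flatnonzero(a2 * 1e6 >= config.de_min_tpm)
    n_de = int(round(config.frac_de * n_expr))
    if n_de > len(eligible):
        raise ConfigError(
            f"frac_de={config.frac_de} requests {n_de} DE genes but only "
            f"{len(eligible)} genes reach de_min_tpm={config.de_min_tpm}"
        )
    de_idx = rng.choice(eligible, size=n_de, replace=False)

    effects = np.zeros(n_expr)
    base_effects = np.array(
        [config.log2_effects[i % len(config.log2_effects)] for i in range(n_de)],
        dtype=float,
    )
    if n_de and np.all(base_effects > 0):
        signs = np.ones(n_de)
        signs[1::2] = -1.0  # symmetric: alternate up/down
        base_effects = base_effects * signs
    effects[de_idx] = base_effects

    a1 = a2 * np.exp2(effects)
    a1 = a1 / a1.sum()

    frame = pd.DataFrame(
        {"abundance1": a1, "abundance2": a2, "log2_effect": effects},
        index=pd.Index(expressed, name="gene"),
    )
    de_genes = frozenset(frame.index[de_idx])
    return GroundTruth(
        frame=frame,
        de_genes=de_genes,
        annotations=annotations if annotations is not None else pd.DataFrame(),
    )


def _mutate_copies(tag_matrix, src, rng, per_base_error):
    """Return mutated copies (>=1 substitution each) of tag_matrix[src]."""
    n = len(src)
    rows = tag_matrix[src].copy()
    # number of substitutions per copy ~ Binomial(17, e) conditioned >= 1
    kmax = 4
    ks = np.arange(1, kmax + 1)
    from scipy.stats import binom as _binom

    pk = _binom.pmf(ks, TAG_LENGTH, per_base_error)
    pk = pk / pk.sum()
    k = rng.choice(ks, size=n, p=pk)

    single = k == 1
    pos = rng.integers(0, TAG_LENGTH, size=single.sum())
    shift = rng.integers(1, 4, size=single.sum())
    idx = np.flatnonzero(single)
    rows[idx, pos] = (rows[idx, pos] + shift) % 4

    for i in np.flatnonzero(~single):
        positions = rng.choice(TAG_LENGTH, size=k[i], replace=False)
        rows[i, positions] = (rows[i, positions] + rng.integers(1, 4, size=k[i])) % 4
    return rows


def _rows_to_tags(rows) -> list:
    return [
        _BASES[r].tobytes().decode("ascii") for r in rows
    ]


def _count_strings(tags) -> dict:
    values, counts = np.unique(np.asarray(tags, dtype=object), return_counts=True)
    return dict(zip(values.tolist(), counts.tolist()))


def _simulate_one_library(
    library_id, n_total, abundances, canonical, tag_matrix, known_tags, config, rng
):
    fracs = [config.frac_adaptor, config.frac_ambiguous_base, config.frac_unknown]
    n_adaptor, n_ambig, n_unknown, n_signal = rng.multinomial(
        n_total, fracs + [1.0 - sum(fracs)]
    )

    counts: dict[str, int] = {}

    def add(tag, c=1):
        counts[tag] = counts.get(tag, 0) + int(c)

    # signal copies, with per-copy substitution errors
    gene_counts = rng.multinomial(n_signal, abundances)
    if config.per_base_error > 0:
        p_any = 1.0 - (1.0 - config.per_base_error) ** TAG_LENGTH
        n_mut = rng.binomial(gene_counts, p_any)
    else:
        n_mut = np.zeros_like(gene_counts)
    intact = gene_counts - n_mut
    for i in np.flatnonzero(intact):
        add(canonical[i], intact[i])
    src = np.repeat(np.arange(len(gene_counts)), n_mut)
    if len(src):
        for tag in _rows_to_tags(_mutate_copies(tag_matrix, src, rng, config.per_base_error)):
            add(tag)

    # ambiguous-base copies: real tags with one position replaced by N
    if n_ambig:
        src = rng.choice(len(abundances), size=n_ambig, p=abundances)
        pos = rng.integers(0, TAG_LENGTH, size=n_ambig)
        for s, p in zip(src, pos):
            t = canonical[s]
            add(t[:p] + "N" + t[p + 1 :])

    # adaptor contamination
    if n_adaptor:
        add(ADAPTOR[:TAG_LENGTH], n_adaptor)

    # tags from sequence absent from the reference
    produced = 0
    while produced < n_unknown:
        batch = rng.integers(0, 4, size=(int((n_unknown - produced) * 1.1) + 8, TAG_LENGTH))
        for tag in _rows_to_tags(batch):
            if tag in known_tags:
                continue
            add(tag)
            produced += 1
            if produced == n_unknown:
                break

    table = TagCountTable.from_counts(library_id, counts, stage="raw")
    assert table.total == n_total
    return table


def simulate_tag_libraries(
    genes: Sequence[GeneRecord],
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[TagCountTable, TagCountTable]:
    """Sample two raw distinct-tag count tables from the ground truth.

    Tag copies are drawn multinomially from each gene's canonical reference
    tag in proportion to true abundance, then corrupted per copy (per-base
    substitution errors, 'N' injection, adaptor contamination, non-reference
    tags).  Distinct-tag counts sum exactly to ``n1`` / ``n2``.
    """
    index = extract_reference_tags(genes)
    expressed = list(truth.frame.index)
    missing = [g for g in expressed if g not in index.canonical_tag]
    if missing:
        raise GenerationError(
            f"expressed gene(s) without a qualifying CATG site: {missing[:5]}"
        )
    canonical = [index.canonical_tag[g] for g in expressed]
    tag_matrix = np.zeros((len(canonical), TAG_LENGTH), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        lut[b] = v
    for i, t in enumerate(canonical):
        tag_matrix[i] = lut[np.frombuffer(t.encode(), dtype=np.uint8)]
    known = set(index.tag_to_genes)

    lib1 = _simulate_one_library(
        "deformed", config.n1, truth.frame["abundance1"].to_numpy(), canonical,
        tag_matrix, known, config, _rng(config, 3),
    )
    lib2 = _simulate_one_library(
        "normal", config.n2, truth.frame["abundance2"].to_numpy(), canonical,
        tag_matrix, known, config, _rng(config, 4),
    )
    return lib1, lib2


def tag_stream(table: TagCountTable) -> np.ndarray:
    """Expand a distinct-tag count table into a per-copy tag array."""
    return np.repeat(
        table.frame["tag"].to_numpy(object), table.frame["count"].to_numpy()
    )


def simulate_study(config: SimConfig):
    """Convenience wrapper: reference, annotations, truth, and both libraries."""
    genes = simulate_reference(config)
    annotations = simulate_annotations(genes, config) if config.n_terms else pd.DataFrame(
        columns=["gene", "term", "namespace"]
    )
    truth = make_ground_truth(genes, config, annotations)
    lib1, lib2 = simulate_tag_libraries(genes, truth, config)
    return genes, annotations, truth, lib1, lib2
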