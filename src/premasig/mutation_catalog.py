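"""Somatic-mutation filtering, trinucleotide 96-channel catalogs, and
strand-symmetric mutation spectra.

Single-base substitutions are collapsed onto the pyrimidine strand and
stratified by the six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
and the 16 combinations of immediate 5'/3' flanking bases, in the COSMIC v2
channel order. A coarser eight-category "pair notation" spectrum (purine-first
labels, CpG split of G:C>A:T, plus an indel bin) supports gene-level spectrum
comparisons such as the TP53 G:C>T:A excess test.

Filtering encodes the FFPE duplicate-concordance design: a somatic call must
be present in both tumor duplicates at sufficient variant allele fraction,
absent from every blood sample of the cohort, rare in the population
(AF <= 0.001), and of a potentially deleterious effect class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_ihc import fisher_exact_2x2


__all__ = [
    "MutationRecord",
    "SomaticFilterConfig",
    "TrinucCatalog",
    "PairSpectrum",
    "CHANNELS",
    "PAIR_CATEGORIES",
    "filter_somatic",
    "classify_channel",
    "to_pair_notation",
    "is_cpg",
    "build_catalog96",
    "build_pair_spectrum",
    "spectrum_compare",
    "mutation_rate_per_mb",
    "read_mutation_tsv",
    "write_mutation_tsv",
    "read_pop_af_tsv",
]

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: COSMIC v2 channel order: substitution class major, then 5' base, then 3' base.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

#: Purine-first pair-notation labels keyed by pyrimidine substitution class.
_PAIR_LABEL = {
    "C>A": "G:C>T:A",
    "C>G": "G:C>C:G",
    "C>T": "G:C>A:T",
    "T>A": "A:T>T:A",
    "T>C": "A:T>G:C",
    "T>G": "A:T>C:G",
}

PAIR_CATEGORIES = (
    "G:C>A:T at CpG",
    "G:C>A:T other",
    "G:C>T:A",
    "G:C>C:G",
    "A:T>G:C",
    "A:T>T:A",
    "A:T>C:G",
    "indel",
)

EFFECT_CLASSES = (
    "synonymous",
    "non-synonymous",
    "nonsense",
    "stop-loss",
    "splice",
    "indel-coding",
    "other",
)

SOURCES = ("tumor_dup1", "tumor_dup2", "blood")


@dataclass(frozen=True)
class MutationRecord:
    """One called variant in one sequencing source of one case."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: Optional[str] = None
    effect: str = "other"
    vaf: Optional[float] = None
    source: str = "tumor_dup1"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not allele or any(b not in BASES for b in allele.upper()):
                raise ValueError(f"{name}={allele!r} is not a non-empty ACGT string")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf={self.vaf} outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity independent of case and source."""
        return (self.chrom, self.pos, self.ref.upper(), self.alt.upper())


@dataclass(frozen=True)
class SomaticFilterConfig:
    vaf_min: float = 0.04
    popaf_max: float = 0.001
    require_both_duplicates: bool = True
    exclude_in_blood: bool = True
    effects_kept: frozenset = frozenset(
        {"splice", "indel-coding", "nonsense", "stop-loss", "non-synonymous"}
    )

    def __post_init__(self) -> None:
        for name in ("vaf_min", "popaf_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def filter_somatic(
    records: Iterable[MutationRecord],
    cfg: SomaticFilterConfig | None = None,
    pop_af: Optional[Mapping[tuple, float]] = None,
    sequenced_sources: Optional[Mapping[str, Iterable[str]]] = None,
) -> list[MutationRecord]:
    """Apply the somatic filtering rules and return one record per case per
    retained variant.

    A variant is retained for a case iff it is called in both tumor
    duplicates (when required) with VAF >= ``vaf_min`` in each, appears in no
    blood sample of the whole cohort, has population allele frequency
    <= ``popaf_max`` (absent from the table counts as 0), and belongs to a
    kept effect class. The emitted record is the duplicate-1 call.

    Which sources were sequenced cannot be told apart from which sources
    yielded calls: a duplicate with zero calls is legitimate data. Pass
    ``sequenced_sources`` (case id -> sources run) when it is known; without
    it, a case whose calls all come from a single tumor source is treated as
    structurally missing its duplicate and rejected by name when duplicate
    concordance is required.
    """
    cfg = cfg or SomaticFilterConfig()
    pop_af = pop_af or {}
    records = list(records)

    blood_keys = {r.key for r in records if r.source == "blood"}

    by_case: dict[str, list[MutationRecord]] = {}
    for r in records:
        by_case.setdefault(r.sample_id, []).append(r)

    retained: list[MutationRecord] = []
    for case_id, case_records in by_case.items():
        if sequenced_sources is not None and case_id in sequenced_sources:
            tumor_sources = {
                s for s in sequenced_sources[case_id] if s != "blood"
            }
        else:
            tumor_sources = {r.source for r in case_records if r.source != "blood"}
        if not tumor_sources:
            continue
        if cfg.require_both_duplicates and len(tumor_sources) < 2:
            raise ValueError(
                f"case {case_id!r} supplies a single tumor source "
                f"({next(iter(tumor_sources))}) but duplicate concordance is required"
            )
        calls: dict[tuple, dict[str, MutationRecord]] = {}
        for r in case_records:
            if r.source == "blood":
                continue
            calls.setdefault(r.key, {})[r.source] = r
        for key, per_source in sorted(calls.items(), key=lambda kv: kv[0]):
            if cfg.require_both_duplicates and set(per_source) != {
                "tumor_dup1",
                "tumor_dup2",
            }:
                continue
            if any(
                r.vaf is None or r.vaf < cfg.vaf_min for r in per_source.values()
            ):
                continue
            if cfg.exclude_in_blood and key in blood_keys:
                continue
            if pop_af.get(key, 0.0) > cfg.popaf_max:
                continue
            rec = per_source.get("tumor_dup1") or next(iter(per_source.values()))
            if rec.effect not in cfg.effects_kept:
                continue
            retained.append(rec)
    return retained


def _normalize(ref: str, alt: str, five: str, three: str) -> tuple[str, str, str, str]:
    """Collapse a substitution with context onto the pyrimidine strand."""
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    for b in (ref, alt, five, three):
        if b not in BASES:
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if ref in "AG":  # purine reference: reverse-complement the whole triplet
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return ref, alt, five, three


def classify_channel(ref: str, alt: str, ctx5: str, ctx3: str) -> int:
    """Map a single-base substitution with flanking bases to its channel
    index (0-95) in the COSMIC v2 ordering."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("classify_channel needs a single-base substitution")
    ref, alt, five, three = _normalize(ref, alt, ctx5, ctx3)
    sub = f"{ref}>{alt}"
    return (
        SUBSTITUTION_CLASSES.index(sub) * 16
        + BASES.index(five) * 4
        + BASES.index(three)
    )


def to_pair_notation(ref: str, alt: str) -> str:
    """Strand-symmetric class of a single-base substitution, purine-first
    label (e.g. both G>T and C>A map to ``G:C>T:A``)."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("to_pair_notation needs a single-base substitution; "
                         "route indels to the indel category upstream")
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return _PAIR_LABEL[f"{ref}>{alt}"]


def is_cpg(ref: str, alt: str, ctx5: str, ctx3: str) -> bool:
    """True iff the substitution sits at a CpG site on the pyrimidine strand
    (normalized reference C immediately followed by G)."""
    ref, _, _, three = _normalize(ref, alt, ctx5, ctx3)
    return ref == "C" and three == "G"


# ---------------------------------------------------------------------------
# reference-context access


def get_context(reference, chrom: str, pos: int) -> tuple[str, str]:
    """5' and 3' bases flanking a 1-based position.

    ``reference`` may be a ``pyfaidx.Fasta`` (or anything indexable the same
    way) or a plain mapping of contig name to sequence string.
    """
    if pos < 2:
        raise ValueError(f"position {pos} too close to the contig start for context")
    if isinstance(reference, Mapping):
        seq = reference[chrom]
        if pos + 1 > len(seq):
            raise ValueError(f"{chrom}:{pos} outside contig of length {len(seq)}")
        triplet = seq[pos - 2 : pos + 1]
    else:
        try:
            triplet = str(reference[chrom][pos - 2 : pos + 1])
        except (KeyError, IndexError) as exc:
            raise ValueError(f"cannot fetch context at {chrom}:{pos}") from exc
        if len(triplet) < 3:
            raise ValueError(f"{chrom}:{pos} outside contig bounds")
    triplet = triplet.upper()
    return triplet[0], triplet[2]


@dataclass
class TrinucCatalog:
    """96 x S matrix of substitution counts with a fixed channel order."""

    samples: list[str]
    counts: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.channels), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.channels)} channels x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.channels), columns=self.samples)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TrinucCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(CHANNELS):
            raise ValueError("catalog TSV does not use the expected channel order")
        return cls(samples=[str(c) for c in df.columns], counts=df.to_numpy())


def build_catalog96(
    mutations: Iterable[MutationRecord],
    reference,
    samples: Optional[Sequence[str]] = None,
) -> tuple[TrinucCatalog, dict[str, int]]:
    """Count SNVs per sample into the 96 channels.

    Non-SNV records (indels, multi-nucleotide substitutions) do not enter the
    catalog; their per-sample counts are returned separately. Sample order is
    first appearance unless ``samples`` is given explicitly.
    """
    mutations = list(mutations)
    if samples is None:
        samples = list(dict.fromkeys(m.sample_id for m in mutations))
    index = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((96, len(samples)), dtype=np.int64)
    other: dict[str, int] = {s: 0 for s in samples}
    for m in mutations:
        j = index.get(m.sample_id)
        if j is None:
            raise ValueError(f"record sample {m.sample_id!r} not in sample list")
        if not m.is_snv:
            other[m.sample_id] += 1
            continue
        five, three = get_context(reference, m.chrom, m.pos)
        counts[classify_channel(m.ref, m.alt, five, three), j] += 1
    return TrinucCatalog(samples=list(samples), counts=counts), other


@dataclass
class PairSpectrum:
    """Counts over the eight strand-symmetric mutation categories."""

    counts: np.ndarray
    name: str = ""
    categories: tuple[str, ...] = PAIR_CATEGORIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.categories),):
            raise ValueError("counts must have one entry per category")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def fractions(self) -> np.ndarray:
        tot = self.total
        return self.counts / tot if tot else np.zeros_like(self.counts, dtype=float)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.categories), name=self.name or None)


def build_pair_spectrum(
    mutations: Iterable[MutationRecord],
    reference=None,
    name: str = "",
) -> PairSpectrum:
    """Assign every mutation to exactly one of the eight categories.

    The CpG split of G:C>A:T needs the 3' flank on the pyrimidine strand, so
    a reference is required whenever the input contains C>T/G>A substitutions.
    """
    counts = np.zeros(len(PAIR_CATEGORIES), dtype=np.int64)
    cat_index = {c: i for i, c in enumerate(PAIR_CATEGORIES)}
    for m in mutations:
        if not m.is_snv:
            counts[cat_index["indel"]] += 1
            continue
        label = to_pair_notation(m.ref, m.alt)
        if label == "G:C>A:T":
            if reference is None:
                raise ValueError(
                    "reference required to split G:C>A:T mutations at CpG sites"
                )
            five, three = get_context(reference, m.chrom, m.pos)
            label = (
                "G:C>A:T at CpG"
                if is_cpg(m.ref, m.alt, five, three)
                else "G:C>A:T other"
            )
        counts[cat_index[label]] += 1
    return PairSpectrum(counts=counts, name=name)


def spectrum_compare(spec_a: PairSpectrum, spec_b: PairSpectrum, category: str) -> float:
    """Two-sided Fisher exact p for one category versus the rest between two
    spectra (e.g. the G:C>T:A excess of one dataset over another)."""
    if category not in spec_a.categories:
        raise KeyError(f"unknown category {category!r}")
    i = spec_a.categories.index(category)
    a_k, b_k = int(spec_a.counts[i]), int(spec_b.counts[i])
    if a_k == 0 and b_k == 0:
        return 1.0
    table = [[a_k, spec_a.total - a_k], [b_k, spec_b.total - b_k]]
    return fisher_exact_2x2(table)


def mutation_rate_per_mb(
    mutations: Iterable[MutationRecord], capture_mb: float = 47.0
) -> tuple[pd.Series, float]:
    """Per-sample mutation rates (count / capture size in Mb) and their mean."""
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    mutations = list(mutations)
    if not mutations:
        raise ValueError("no mutations supplied")
    counts = pd.Series([m.sample_id for m in mutations]).value_counts().sort_index()
    rates = counts / capture_mb
    rates.name = "mutations_per_mb"
    return rates, float(rates.mean())


def panel_summary(
    mutations: Iterable[MutationRecord],
    n_cases: int,
    genes: Optional[Sequence[str]] = None,
) -> tuple[float, pd.Series]:
    """Case-level mutation burden of a gene panel.

    Returns the fraction of cases carrying at least one (filtered) mutation,
    and the per-gene fraction of cases mutated. ``n_cases`` is the number of
    sequenced cases (the denominator), which may exceed the number of cases
    with retained mutations.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be positive")
    mutations = list(mutations)
    mutated_cases = {m.sample_id for m in mutations}
    if len(mutated_cases) > n_cases:
        raise ValueError("more mutated cases than n_cases")
    per_gene: dict[str, set] = {}
    for m in mutations:
        if m.gene is not None:
            per_gene.setdefault(m.gene, set()).add(m.sample_id)
    if genes is None:
        genes = sorted(per_gene)
    freqs = pd.Series(
        {g: len(per_gene.get(g, set())) / n_cases for g in genes}, name="case_frequency"
    )
    return len(mutated_cases) / n_cases, freqs


# ---------------------------------------------------------------------------
# TSV interfaces (MAF-like mutation table, population allele frequencies)

_MUTATION_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "vaf",
    "source",
]


def read_mutation_tsv(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    records = []
    for _, row in df.iterrows():
        vaf = row.get("vaf")
        gene = row.get("gene")
        records.append(
            MutationRecord(
                sample_id=str(row["sample_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=None if pd.isna(gene) else str(gene),
                effect=str(row.get("effect", "other")),
                vaf=None if pd.isna(vaf) else float(vaf),
                source=str(row.get("source", "tumor_dup1")),
            )
        )
    return records


def write_mutation_tsv(records: Iterable[MutationRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_MUTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_pop_af_tsv(path) -> dict[tuple, float]:
    """Population allele-frequency table keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos), str(r.ref).upper(), str(r.alt).upper()): float(r.af)
        for r in df.itertuples()
    }
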