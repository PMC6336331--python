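"""Synthetic cohorts, call sets, and catalogs with known ground truth.

Every downstream stage of the pipeline — subtype calling, somatic filtering,
spectrum construction, signature extraction, exposure estimation, and the
permutation tests — can be exercised on data generated here, where the truth
is recorded and recoverable. The generators emulate the statistical structure
of a small premenopausal breast-cancer cohort:

* subtype mixture defaulting to luminal A 58%, triple-negative 21%, luminal B
  11%, HER2-enriched 5%, undetermined 6%, with per-subtype Ki67-positivity
  rates (72% in luminal A up to 98% in triple-negative);
* an 8-gene targeted panel with per-subtype mutation probabilities tuned to
  case-level frequencies around TP53 33%, PIK3CA 21%, AKT1 9%;
* tumor-duplicate call sets in which true somatic variants pass every filter
  and injected artifacts each violate exactly one rule (single duplicate,
  blood contamination, common population allele, sub-threshold VAF);
* 96-channel catalogs sampled as Poisson totals and multinomial channel
  draws from known signature mixtures with Dirichlet per-sample exposures;
* a TP53-like mutation spectrum with a configurable G:C>T:A weight
  (default 0.27) over the eight strand-symmetric categories.

All generators are pure functions of their configuration: the same seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_ihc import IHCRecord
from .mutation_catalog import BASES, PAIR_CATEGORIES, MutationRecord, TrinucCatalog

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_reference",
    "write_fasta",
    "make_signatures",
    "simulate_cohort",
    "simulate_callsets",
    "simulate_catalog",
    "simulate_tp53_spectrum",
    "simulate_covariates",
]

# Observed cohort composition as exact count fractions (134/26/11/48/14 of
# 233); the corresponding rounded percentages (58/11/5/21/6) sum to 101%, so
# the counts are the usable probability vector.
DEFAULT_SUBTYPE_PROBS = {
    "LuminalA": 134 / 233,
    "TripleNegative": 48 / 233,
    "LuminalB": 26 / 233,
    "HER2enriched": 11 / 233,
    "Undetermined": 14 / 233,
}

DEFAULT_KI67_POS_RATES = {
    "LuminalA": 0.72,
    "LuminalB": 0.88,
    "HER2enriched": 0.91,
    "TripleNegative": 0.98,
    "Undetermined": 0.93,
}

#: Per-subtype probability that a case carries a deleterious mutation in each
#: panel gene; marginals approximate case-level frequencies of TP53 ~33%,
#: PIK3CA ~21%, AKT1 ~9%, others below 5%.
DEFAULT_GENE_PANEL = {
    "TP53": {"LuminalA": 0.21, "LuminalB": 0.35, "HER2enriched": 0.70,
             "TripleNegative": 0.60, "Undetermined": 0.30},
    "PIK3CA": {"LuminalA": 0.23, "LuminalB": 0.30, "HER2enriched": 0.20,
               "TripleNegative": 0.10, "Undetermined": 0.20},
    "AKT1": {"LuminalA": 0.14, "LuminalB": 0.04, "HER2enriched": 0.02,
             "TripleNegative": 0.02, "Undetermined": 0.05},
    "CDH1": {"LuminalA": 0.06, "LuminalB": 0.04, "HER2enriched": 0.02,
             "TripleNegative": 0.02, "Undetermined": 0.04},
    "ERBB2": {"LuminalA": 0.02, "LuminalB": 0.04, "HER2enriched": 0.10,
              "TripleNegative": 0.02, "Undetermined": 0.02},
    "NOTCH1": {"LuminalA": 0.02, "LuminalB": 0.02, "HER2enriched": 0.02,
               "TripleNegative": 0.06, "Undetermined": 0.02},
    "PTEN": {"LuminalA": 0.02, "LuminalB": 0.02, "HER2enriched": 0.02,
             "TripleNegative": 0.08, "Undetermined": 0.02},
    "RB1": {"LuminalA": 0.01, "LuminalB": 0.02, "HER2enriched": 0.02,
            "TripleNegative": 0.10, "Undetermined": 0.02},
}

#: Eight-category spectrum weights; the G:C>T:A weight of 0.27 is the
#: headline excess being emulated.
DEFAULT_TP53_SPECTRUM = {
    "G:C>A:T at CpG": 0.14,
    "G:C>A:T other": 0.12,
    "G:C>T:A": 0.27,
    "G:C>C:G": 0.08,
    "A:T>G:C": 0.12,
    "A:T>T:A": 0.06,
    "A:T>C:G": 0.06,
    "indel": 0.15,
}

_EFFECT_WEIGHTS = {
    "non-synonymous": 0.70,
    "nonsense": 0.10,
    "indel-coding": 0.10,
    "splice": 0.05,
    "stop-loss": 0.05,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic generators. ``seed`` is mandatory."""

    seed: int
    # cohort
    n_cases: int = 229
    subtype_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS)
    )
    ki67_pos_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KI67_POS_RATES)
    )
    basal_rate: float = 0.94
    # targeted panel call sets
    gene_panel: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_GENE_PANEL.items()}
    )
    artifact_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "single_duplicate": 0.3,
            "blood_present": 0.3,
            "pop_af": 0.3,
            "low_vaf": 0.3,
        }
    )
    vaf_beta: tuple[float, float] = (5.0, 15.0)
    vaf_min: float = 0.04
    # signature catalogs
    n_samples: int = 30
    n_signatures: int = 3
    mutations_per_sample_mean: float = 1000.0
    dirichlet_alpha: float = 1.0
    true_signatures: Optional[np.ndarray] = None
    # TP53-like spectrum
    tp53_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TP53_SPECTRUM)
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("subtype_probs", "tp53_spectrum"):
            probs = np.array(list(getattr(self, name).values()), dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {probs.sum():.12f})")
            if (probs < 0).any():
                raise ValueError(f"{name} has negative entries")
        if set(self.tp53_spectrum) != set(PAIR_CATEGORIES):
            raise ValueError("tp53_spectrum must cover exactly the 8 categories")


@dataclass
class SimTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    subtypes: Optional[dict[str, str]] = None
    ki67_positive: Optional[dict[str, bool]] = None
    gene_hits: Optional[dict[str, list[str]]] = None
    true_variants: Optional[list[tuple]] = None  # (case_id, variant key)
    artifacts: Optional[list[tuple]] = None  # (case_id, variant key, rule violated)
    signatures: Optional[np.ndarray] = None
    exposures: Optional[np.ndarray] = None  # K x S, columns sum to 1
    spectrum_probs: Optional[dict[str, float]] = None
    sequenced_sources: Optional[dict[str, set]] = None


# ---------------------------------------------------------------------------
# reference sequence


def simulate_reference(
    contigs: Sequence[str], length: int, seed: int
) -> dict[str, str]:
    """I.i.d. uniform random sequences, one per requested contig."""
    if length < 3:
        raise ValueError("contig length must be >= 3")
    rng = np.random.default_rng(seed)
    return {
        name: "".join(rng.choice(list(BASES), size=length))
        for name in contigs
    }


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# signatures


def make_signatures(
    k: int,
    seed,
    max_pairwise_cosine: float = 0.6,
    concentration: float = 0.1,
    n_channels: int = 96,
    max_tries: int = 1000,
) -> np.ndarray:
    """Draw ``k`` sparse random signatures (Dirichlet with small
    concentration) whose pairwise cosine similarities stay below the bound,
    so they are well separated and recoverable."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        W = rng.dirichlet(np.full(n_channels, concentration), size=k).T
        norms = np.linalg.norm(W, axis=0)
        gram = (W / norms).T @ (W / norms)
        off = gram[~np.eye(k, dtype=bool)]
        if (off < max_pairwise_cosine).all():
            return W
    raise RuntimeError("could not draw sufficiently separated signatures")


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(cfg: SimConfig) -> tuple[list[IHCRecord], SimTruth]:
    """Draw cases with marker values consistent with their drawn subtype."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    subtype_names = list(cfg.subtype_probs)
    probs = np.array([cfg.subtype_probs[s] for s in subtype_names])

    records: list[IHCRecord] = []
    subtypes: dict[str, str] = {}
    ki67_truth: dict[str, bool] = {}
    for i in range(cfg.n_cases):
        case_id = f"case{i:04d}"
        subtype = subtype_names[rng.choice(len(subtype_names), p=probs)]
        er_pos_pct = lambda: float(rng.uniform(5, 100))
        neg_pct = lambda: float(rng.uniform(0, 1))

        her2 = "negative"
        fish = False
        egfr = ck56 = False
        if subtype == "LuminalA":
            er, pr = er_pos_pct(), (er_pos_pct() if rng.random() < 0.85 else neg_pct())
        elif subtype == "LuminalB":
            er, pr = er_pos_pct(), (er_pos_pct() if rng.random() < 0.7 else neg_pct())
            her2 = "positive"
        elif subtype == "HER2enriched":
            er, pr = neg_pct(), neg_pct()
            her2 = "positive"
        elif subtype == "TripleNegative":
            er, pr = neg_pct(), neg_pct()
            if rng.random() < cfg.basal_rate:
                egfr = bool(rng.random() < 0.8)
                ck56 = bool(rng.random() < 0.6) or not egfr
        else:  # Undetermined: mostly equivocal HER2 without FISH
            if rng.random() < 13 / 14:
                er, pr = er_pos_pct(), er_pos_pct()
                her2 = "equivocal"
            else:  # the rare ER-/PR+/HER2- pattern
                er, pr = neg_pct(), float(rng.uniform(2, 30))

        ki67_pos = bool(rng.random() < cfg.ki67_pos_rates[subtype])
        ki67 = float(rng.uniform(14.5, 100)) if ki67_pos else float(rng.uniform(0, 14))
        records.append(
            IHCRecord(
                case_id=case_id,
                er_pct=er,
                pr_pct=pr,
                her2=her2,
                ki67_pct=ki67,
                egfr_pos=egfr,
                ck56_pos=ck56,
                p53_stain="positive" if rng.random() < 0.5 else "null",
                fish_confirmed=fish,
            )
        )
        subtypes[case_id] = subtype
        ki67_truth[case_id] = ki67_pos
    return records, SimTruth(subtypes=subtypes, ki67_positive=ki67_truth)


def cohort_to_frame(records: list[IHCRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# targeted-panel call sets


def _draw_vaf(rng: np.random.Generator, cfg: SimConfig) -> float:
    """Tumor-fraction-like VAF from Beta(5, 15) truncated at the calling
    threshold, so true somatic calls always pass the VAF filter."""
    a, b = cfg.vaf_beta
    while True:
        v = float(rng.beta(a, b))
        if v >= cfg.vaf_min:
            return v


def simulate_callsets(
    cfg: SimConfig,
    subtypes: Optional[Mapping[str, str]] = None,
) -> tuple[list[MutationRecord], dict[tuple, float], SimTruth]:
    """Per-case tumor-duplicate (and blood) call sets.

    True somatic variants are gene-panel hits drawn from the per-subtype
    probabilities; they appear in both duplicates with VAF above threshold.
    Injected artifacts violate exactly one filtering rule each and are placed
    at positions distinct from any true variant. Returns the records, the
    population allele-frequency table for the pop-AF artifacts, and the truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    if subtypes is None:
        _, truth = simulate_cohort(cfg)
        subtypes = truth.subtypes

    records: list[MutationRecord] = []
    pop_af: dict[tuple, float] = {}
    true_variants: list[tuple] = []
    artifacts: list[tuple] = []
    gene_hits: dict[str, list[str]] = {}
    effects = list(_EFFECT_WEIGHTS)
    effect_p = np.array(list(_EFFECT_WEIGHTS.values()))
    pos_counter = 10  # global position allocator keeps variant keys unique

    def next_pos() -> int:
        nonlocal pos_counter
        pos_counter += 10
        return pos_counter

    def random_snv(rng) -> tuple[str, str]:
        ref = BASES[rng.integers(4)]
        alt = rng.choice([b for b in BASES if b != ref])
        return ref, str(alt)

    for case_id in sorted(subtypes):
        subtype = subtypes[case_id]
        hits = []
        for gene, per_subtype in cfg.gene_panel.items():
            if rng.random() >= per_subtype.get(subtype, 0.0):
                continue
            hits.append(gene)
            pos = next_pos()
            effect = str(rng.choice(effects, p=effect_p))
            if effect == "indel-coding":
                ref, alt = "AT", "A"
            else:
                ref, alt = random_snv(rng)
            key = ("chr1", pos, ref, alt)
            for source in ("tumor_dup1", "tumor_dup2"):
                records.append(
                    MutationRecord(
                        sample_id=case_id, chrom="chr1", pos=pos, ref=ref, alt=alt,
                        gene=gene, effect=effect, vaf=_draw_vaf(rng, cfg),
                        source=source,
                    )
                )
            true_variants.append((case_id, key))
        gene_hits[case_id] = hits

        for rule, rate in cfg.artifact_rates.items():
            for _ in range(rng.poisson(rate)):
                pos = next_pos()
                ref, alt = random_snv(rng)
                key = ("chr1", pos, ref, alt)
                common = dict(sample_id=case_id, chrom="chr1", pos=pos, ref=ref,
                              alt=alt, gene=None, effect="non-synonymous")
                if rule == "single_duplicate":
                    records.append(MutationRecord(
                        **common, vaf=_draw_vaf(rng, cfg), source="tumor_dup1"))
                elif rule == "blood_present":
                    for source in ("tumor_dup1", "tumor_dup2", "blood"):
                        records.append(MutationRecord(
                            **common, vaf=_draw_vaf(rng, cfg), source=source))
                elif rule == "pop_af":
                    for source in ("tumor_dup1", "tumor_dup2"):
                        records.append(MutationRecord(
                            **common, vaf=_draw_vaf(rng, cfg), source=source))
                    pop_af[key] = 0.005
                elif rule == "low_vaf":
                    for source in ("tumor_dup1", "tumor_dup2"):
                        records.append(MutationRecord(
                            **common, vaf=float(rng.uniform(0.005, 0.035)),
                            source=source))
                else:
                    raise ValueError(f"unknown artifact rule {rule!r}")
                artifacts.append((case_id, key, rule))

    # every case is sequenced in both duplicates plus blood, whether or not
    # calls were made in each — recorded so the filter can tell a clean
    # duplicate from a missing one
    truth = SimTruth(
        subtypes=dict(subtypes),
        gene_hits=gene_hits,
        true_variants=true_variants,
        artifacts=artifacts,
        sequenced_sources={
            c: {"tumor_dup1", "tumor_dup2", "blood"} for c in subtypes
        },
    )
    return records, pop_af, truth


# ---------------------------------------------------------------------------
# signature catalogs


def simulate_catalog(cfg: SimConfig) -> tuple[TrinucCatalog, SimTruth]:
    """Sample a 96 x S catalog from a known signature mixture.

    Per sample: exposures e ~ Dirichlet(alpha), total n ~ Poisson(mean),
    channel counts ~ Multinomial(n, W e).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    W = cfg.true_signatures
    if W is None:
        W = make_signatures(cfg.n_signatures, np.random.SeedSequence([cfg.seed, 30]))
    W = np.asarray(W, dtype=float)
    if not np.allclose(W.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("true signatures must be column-stochastic")
    k = W.shape[1]

    exposures = rng.dirichlet(np.full(k, cfg.dirichlet_alpha), size=cfg.n_samples).T
    counts = np.zeros((W.shape[0], cfg.n_samples), dtype=np.int64)
    for j in range(cfg.n_samples):
        n = rng.poisson(cfg.mutations_per_sample_mean)
        if n:
            counts[:, j] = rng.multinomial(n, W @ exposures[:, j])
    catalog = TrinucCatalog(
        samples=[f"sample{j:03d}" for j in range(cfg.n_samples)], counts=counts
    )
    return catalog, SimTruth(signatures=W, exposures=exposures)


# ---------------------------------------------------------------------------
# TP53-like spectrum


_CATEGORY_PYRIMIDINE = {
    "G:C>T:A": ("C", "A"),
    "G:C>C:G": ("C", "G"),
    "A:T>G:C": ("T", "C"),
    "A:T>T:A": ("T", "A"),
    "A:T>C:G": ("T", "G"),
}


def simulate_tp53_spectrum(
    cfg: SimConfig, n_mutations: int
) -> tuple[list[MutationRecord], dict[str, str]]:
    """Mutations drawn from the eight-category spectrum, embedded in a
    synthetic contig whose local context realizes each category (a CpG-class
    mutation sits on a pyrimidine-strand C followed by G). Half the
    substitutions are emitted on the purine strand to exercise strand
    collapsing. Returns the records and the synthetic reference."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    cats = list(PAIR_CATEGORIES)
    weights = np.array([cfg.tp53_spectrum[c] for c in cats])
    draws = rng.choice(len(cats), size=n_mutations, p=weights)

    contig = "TP53_synth"
    seq = np.full(10 * n_mutations + 20, "A", dtype="<U1")
    records: list[MutationRecord] = []
    for i, ci in enumerate(draws):
        cat = cats[ci]
        pos = 10 * i + 15  # 1-based center position
        if cat == "indel":
            seq[pos - 2 : pos + 1] = list("CAT")
            ref, alt, effect = "AT", "A", "indel-coding"
        else:
            if cat == "G:C>A:T at CpG":
                ref, alt = "C", "T"
                five, three = str(rng.choice(list(BASES))), "G"
            elif cat == "G:C>A:T other":
                ref, alt = "C", "T"
                five = str(rng.choice(list(BASES)))
                three = str(rng.choice(["A", "C", "T"]))
            else:
                ref, alt = _CATEGORY_PYRIMIDINE[cat]
                five = str(rng.choice(list(BASES)))
                three = str(rng.choice(list(BASES)))
            if rng.random() < 0.5:  # emit on the purine strand
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
                five, three = _COMPLEMENT[three], _COMPLEMENT[five]
            seq[pos - 2 : pos + 1] = [five, ref, three]
            effect = "non-synonymous"
        records.append(
            MutationRecord(
                sample_id="TP53_SIM", chrom=contig, pos=pos, ref=ref, alt=alt,
                gene="TP53", effect=effect, vaf=0.3, source="tumor_dup1",
            )
        )
    return records, {contig: "".join(seq)}


# ---------------------------------------------------------------------------
# covariates for association studies


def simulate_covariates(
    sample_ids: Sequence[str],
    seed: int,
    subtype_probs: Optional[Mapping[str, float]] = None,
    menopausal_p: float = 0.5,
    source_p: float = 0.5,
) -> pd.DataFrame:
    """Independent categorical covariates (IHC subtype, menopausal status,
    study source) for permutation-test studies; drawn independently of any
    exposure values so the null holds by construction."""
    rng = np.random.default_rng(seed)
    probs = dict(subtype_probs or DEFAULT_SUBTYPE_PROBS)
    names = list(probs)
    p = np.array([probs[s] for s in names])
    n = len(sample_ids)
    df = pd.DataFrame(
        {
            "subtype": [names[i] for i in rng.choice(len(names), size=n, p=p)],
            "menopausal": np.where(rng.random(n) < menopausal_p, "pre", "post"),
            "source": np.where(rng.random(n) < source_p, "PRECAMA", "TCGA"),
            "is_tn": np.zeros(n, dtype=bool),
        },
        index=[str(s) for s in sample_ids],
    )
    df["is_tn"] = df["subtype"] == "TripleNegative"
    return df
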