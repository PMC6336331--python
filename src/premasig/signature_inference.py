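"""Mutational-signature extraction by non-negative matrix factorization.

A 96 x S catalog V is factorized as V ~ W H with W >= 0 (96 x K signatures)
and H >= 0 (K x S exposures), minimizing the generalized Kullback-Leibler
divergence D(V || WH) by multiplicative updates (Brunet et al. style); a
Frobenius objective is available behind a flag. Stability-based rank
selection runs many random restarts per rank and scores two things: the
cophenetic correlation of the sample consensus matrix (connectivity by each
run's dominant signature) and the reproducibility of the signature vectors
themselves across restarts, which is what actually breaks the tie between
the true rank and smaller ones.
Extracted signatures are matched to a reference catalog (e.g. COSMIC v2) by
cosine similarity, and per-sample contributions are re-estimated by
non-negative least squares against the normalized signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment, nnls
from scipy.spatial.distance import squareform

from .mutation_catalog import CHANNELS, TrinucCatalog

__all__ = [
    "SignatureSet",
    "ExposureMatrix",
    "NMFResult",
    "ConsensusResult",
    "RankSelection",
    "ReferenceCatalog",
    "nmf_factorize",
    "run_multistart",
    "select_rank",
    "cosine_similarity",
    "match_signatures",
    "estimate_exposures",
    "best_assignment",
]

_EPS = 1e-12  # guards multiplicative-update denominators and logs

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def _as_matrix(catalog) -> tuple[np.ndarray, list[str]]:
    if isinstance(catalog, TrinucCatalog):
        return catalog.counts.astype(float), list(catalog.samples)
    arr = np.asarray(catalog, dtype=float)
    return arr, [f"S{j}" for j in range(arr.shape[1])]


@dataclass
class SignatureSet:
    """Column-stochastic 96 x K signature matrix with per-column labels."""

    W: np.ndarray
    labels: list[str]
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[1] != len(self.labels):
            raise ValueError("W must be channels x len(labels)")
        if (self.W < 0).any():
            raise ValueError("signatures must be non-negative")
        sums = self.W.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signature columns must sum to 1 (within 1e-9)")

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=list(self.channels), columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SignatureSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(W=df.to_numpy(), labels=[str(c) for c in df.columns],
                   channels=tuple(df.index))


@dataclass
class ExposureMatrix:
    """K x S non-negative contributions of signatures to samples."""

    H: np.ndarray
    signatures: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape != (len(self.signatures), len(self.samples)):
            raise ValueError("H shape must be signatures x samples")
        if (self.H < -1e-12).any():
            raise ValueError("exposures must be non-negative")
        self.H = np.clip(self.H, 0.0, None)

    @property
    def zero_samples(self) -> list[str]:
        """Samples with no attributed mutations (all-zero columns)."""
        return [s for j, s in enumerate(self.samples) if self.H[:, j].sum() == 0]

    def percent(self) -> pd.DataFrame:
        """Columns rescaled to sum to 100; zero-mutation samples stay all-zero."""
        sums = self.H.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, self.H / sums * 100.0, 0.0)
        return pd.DataFrame(pct, index=self.signatures, columns=self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.H, index=self.signatures, columns=self.samples)


@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    trace: np.ndarray  # objective after every iteration


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * (np.log(V[mask]) - np.log(WH[mask] + _EPS))
    return float(term.sum() - V.sum() + WH.sum())


def _rng_from(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def nmf_factorize(
    catalog,
    rank: int,
    seed: SeedLike = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    objective: str = "kl",
) -> NMFResult:
    """Factorize a catalog into ``rank`` signatures and their exposures.

    Multiplicative updates for the chosen objective ("kl" = generalized
    Kullback-Leibler divergence, "frobenius" = squared error); both keep the
    factors non-negative and the objective non-increasing. Iteration stops at
    ``max_iter`` or when the relative objective change drops below ``tol``.
    W is column-normalized on return, with the scale moved into H.
    """
    V, _ = _as_matrix(catalog)
    m, n = V.shape
    if (V < 0).any():
        raise ValueError("catalog must be non-negative")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank >= min(m, n):
        raise ValueError(
            f"rank {rank} must be smaller than min(channels, samples) = {min(m, n)}"
        )
    zero_cols = np.where(V.sum(axis=0) == 0)[0]
    if zero_cols.size:
        raise ValueError(
            f"all-zero sample columns {zero_cols.tolist()}: drop these samples first"
        )
    if objective not in ("kl", "frobenius"):
        raise ValueError("objective must be 'kl' or 'frobenius'")

    rng = _rng_from(seed)
    scale = V.mean()
    W = rng.uniform(0.0, 1.0, size=(m, rank)) * scale
    H = rng.uniform(0.0, 1.0, size=(rank, n)) * scale

    trace = np.empty(max_iter)
    prev = np.inf
    n_iter = 0
    converged = False
    for it in range(max_iter):
        if objective == "kl":
            WH = W @ H
            H *= (W.T @ (V / (WH + _EPS))) / (W.sum(axis=0)[:, None] + _EPS)
            WH = W @ H
            W *= ((V / (WH + _EPS)) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
            obj = _kl_divergence(V, W @ H)
        else:
            H *= (W.T @ V) / (W.T @ W @ H + _EPS)
            W *= (V @ H.T) / (W @ H @ H.T + _EPS)
            diff = V - W @ H
            obj = float((diff * diff).sum())
        trace[it] = obj
        n_iter = it + 1
        if np.isfinite(prev) and prev > 0 and abs(prev - obj) / prev < tol:
            converged = True
            break
        prev = obj

    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col
    H = H * col[:, None]
    return NMFResult(W=W, H=H, objective=float(trace[n_iter - 1]), n_iter=n_iter,
                     converged=converged, trace=trace[:n_iter].copy())


@dataclass
class ConsensusResult:
    rank: int
    consensus: np.ndarray
    cophenetic: float
    best_run: NMFResult
    objectives: np.ndarray
    #: mean over restarts of the worst-matched cosine between each run's
    #: signatures and the best run's (1 = every restart reproduces every
    #: signature; spurious components of an over-factorized rank drag it down)
    signature_stability: float = 1.0


def _cophenetic(consensus: np.ndarray) -> float:
    """Cophenetic correlation of 1-consensus distances under average linkage.

    Degenerate cases (a single sample pair, or all distances equal as in a
    perfectly stable consensus of one cluster) are defined as 1.
    """
    n = consensus.shape[0]
    if n < 3:
        return 1.0
    d = squareform(1.0 - consensus, checks=False)
    if np.std(d) < 1e-12:
        return 1.0
    Z = hierarchy.linkage(d, method="average")
    coph, _ = hierarchy.cophenet(Z, d)
    if not np.isfinite(coph):
        return 1.0
    return float(coph)


def run_multistart(
    catalog,
    rank: int,
    n_runs: int = 50,
    seed: SeedLike = None,
    **nmf_kwargs,
) -> ConsensusResult:
    """Repeat the factorization from random starts and summarize stability.

    Each run contributes a connectivity matrix (two samples connected when
    they share the same dominant signature); the consensus matrix is their
    mean and its cophenetic correlation measures how reproducible the sample
    clustering is across restarts. The run with the lowest objective is kept.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    V, _ = _as_matrix(catalog)
    n = V.shape[1]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_runs)

    consensus = np.zeros((n, n))
    runs: list[NMFResult] = []
    objectives = np.empty(n_runs)
    for r, child in enumerate(children):
        res = nmf_factorize(V, rank, seed=np.random.default_rng(child), **nmf_kwargs)
        labels = res.H.argmax(axis=0)
        consensus += (labels[:, None] == labels[None, :]).astype(float)
        objectives[r] = res.objective
        runs.append(res)
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    best = min(runs, key=lambda r: r.objective)

    coph = 1.0 if rank == 1 else _cophenetic(consensus)
    if rank == 1:
        stability = 1.0
    else:
        worst = [best_assignment(best.W, r.W)[1].min() for r in runs]
        stability = float(np.mean(worst))
    return ConsensusResult(rank=rank, consensus=consensus, cophenetic=coph,
                           best_run=best, objectives=objectives,
                           signature_stability=stability)


@dataclass
class RankSelection:
    rank: int
    curve: pd.DataFrame  # columns: rank, cophenetic, best_objective
    results: dict[int, ConsensusResult]


def select_rank(
    catalog,
    rank_range: Sequence[int],
    n_runs: int = 50,
    seed: SeedLike = None,
    stability_threshold: float = 0.95,
    **nmf_kwargs,
) -> RankSelection:
    """Choose the number of signatures from the stability of repeated
    factorizations.

    A rank smaller than the true one clusters samples just as reproducibly
    as the true rank (the forced merge is deterministic), so the cophenetic
    coefficient alone plateaus at 1 below the truth and cannot choose between
    tied ranks. Selection therefore keys on signature-level reproducibility:
    the chosen rank is the largest one whose every signature is reproduced
    across restarts (mean worst-matched cosine >= ``stability_threshold``);
    spurious components of an over-factorized rank differ between restarts
    and fail the bar. If no rank qualifies, the rank maximizing the
    cophenetic coefficient is returned, ties broken toward the smaller rank.
    The full curve (cophenetic, signature stability, best objective) is
    returned for inspection.
    """
    ranks = sorted(set(int(r) for r in rank_range))
    if not ranks:
        raise ValueError("empty rank range")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(ranks))
    results: dict[int, ConsensusResult] = {}
    rows = []
    for rank, child in zip(ranks, children):
        res = run_multistart(catalog, rank, n_runs=n_runs, seed=child, **nmf_kwargs)
        results[rank] = res
        rows.append(
            {"rank": rank, "cophenetic": res.cophenetic,
             "signature_stability": res.signature_stability,
             "best_objective": res.best_run.objective}
        )
    curve = pd.DataFrame(rows)
    stable = curve[curve["signature_stability"] >= stability_threshold]
    if len(stable):
        best_rank = int(stable["rank"].max())
    else:
        # idxmax returns the first maximum; ranks ascend, so ties resolve
        # toward the smaller rank
        best_rank = int(curve.loc[curve["cophenetic"].idxmax(), "rank"])
    return RankSelection(rank=best_rank, curve=curve, results=results)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class ReferenceCatalog:
    """Named reference signatures over the 96 channels (e.g. COSMIC v2)."""

    matrix: np.ndarray
    names: list[str]
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.channels), len(self.names)):
            raise ValueError("matrix must be channels x names")
        if (self.matrix < 0).any():
            raise ValueError("reference signatures must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("reference signatures must each sum to 1")

    @classmethod
    def from_tsv(cls, path) -> "ReferenceCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=df.to_numpy(), names=[str(c) for c in df.columns],
                   channels=tuple(df.index))


def match_signatures(
    extracted: SignatureSet,
    reference: ReferenceCatalog,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Best reference hit per extracted signature by cosine similarity.

    Matching is independent per extracted signature (several may share a best
    hit); hits below ``threshold`` are flagged unmatched. Channel orders must
    agree exactly — no silent reordering.
    """
    if tuple(extracted.channels) != tuple(reference.channels):
        raise ValueError("channel order mismatch between extracted and reference")
    rows = []
    for j, label in enumerate(extracted.labels):
        sims = np.array(
            [cosine_similarity(extracted.W[:, j], reference.matrix[:, i])
             for i in range(len(reference.names))]
        )
        i = int(sims.argmax())
        rows.append(
            {"signature": label, "best_match": reference.names[i],
             "cosine": float(sims[i]), "below_threshold": bool(sims[i] < threshold)}
        )
    return pd.DataFrame(rows)


def best_assignment(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal one-to-one column matching between two non-negative
    matrices, maximizing total cosine similarity (Hungarian algorithm).
    Intended for recovery checks against known ground-truth factors."""
    ka, kb = A.shape[1], B.shape[1]
    sim = np.array(
        [[cosine_similarity(A[:, i], B[:, j]) for j in range(kb)] for i in range(ka)]
    )
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]


def estimate_exposures(catalog, signatures: SignatureSet) -> ExposureMatrix:
    """Per-sample non-negative least-squares fit of counts on the signature
    matrix. Samples without mutations get all-zero exposures (listed in
    ``ExposureMatrix.zero_samples``)."""
    V, samples = _as_matrix(catalog)
    if V.shape[0] != signatures.W.shape[0]:
        raise ValueError("catalog and signatures disagree on channel count")
    K = signatures.k
    H = np.zeros((K, V.shape[1]))
    for j in range(V.shape[1]):
        if V[:, j].sum() == 0:
            continue
        H[:, j], _ = nnls(signatures.W, V[:, j])
    return ExposureMatrix(H=H, signatures=list(signatures.labels), samples=samples)
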