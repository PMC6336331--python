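"""Permutation tests of signature contributions against categorical
covariates.

The test statistic is the tie-corrected Kruskal-Wallis H. Because cohorts
here are small and contributions are far from any asymptotic regime, p-values
are empirical: the statistic is recomputed over label permutations (default
2000) and the add-one estimator p = (1 + #{H* >= H}) / (1 + n_perm) is
reported, so p can never be exactly zero and is floored at 1/(n_perm + 1).

Supported designs:

* plain            — unrestricted permutations of group labels;
* stratified       — permutations only within strata (e.g. menopausal status
                     within IHC subtype);
* adjusted         — Freedman-Lane residual permutation against an indicator
                     design of nuisance covariates (e.g. menopausal status
                     adjusted for subtype by linear model);
* subset           — any of the above restricted by an inclusion mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signature_inference import ExposureMatrix

__all__ = [
    "SampleCovariates",
    "AssociationResult",
    "VariantSpec",
    "kruskal_wallis_statistic",
    "permutation_test",
    "run_panel",
]


@dataclass
class SampleCovariates:
    """Covariate assignment for the samples of one test.

    ``group`` is the factor under test; ``strata`` restricts permutations;
    ``adjust`` holds nuisance covariates removed by linear regression before
    permuting (Freedman-Lane); ``include`` subsets the samples first.
    """

    sample_ids: list[str]
    group: np.ndarray
    strata: Optional[np.ndarray] = None
    adjust: Optional[pd.DataFrame] = None
    include: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.group = np.asarray(self.group)
        if len(self.group) != n:
            raise ValueError("group length must match sample_ids")
        if self.strata is not None:
            self.strata = np.asarray(self.strata)
            if len(self.strata) != n:
                raise ValueError("strata length must match sample_ids")
        if self.adjust is not None:
            self.adjust = pd.DataFrame(self.adjust)
            if len(self.adjust) != n:
                raise ValueError("adjust rows must match sample_ids")
        if self.include is not None:
            self.include = np.asarray(self.include, dtype=bool)
            if len(self.include) != n:
                raise ValueError("include length must match sample_ids")
        if self.strata is not None and self.adjust is not None:
            raise ValueError("stratified and adjusted designs cannot be combined")

    @property
    def variant(self) -> str:
        if self.adjust is not None:
            return "adjusted"
        if self.strata is not None:
            return "stratified"
        if self.include is not None:
            return "subset"
        return "plain"


@dataclass
class AssociationResult:
    statistic: float
    p_empirical: float
    n_perm: int
    variant: str
    seed: Optional[int] = None
    signature: Optional[str] = None


def kruskal_wallis_statistic(values, groups) -> float:
    """Tie-corrected Kruskal-Wallis H.

    H = [12/(N(N+1)) * sum_i R_i^2/n_i - 3(N+1)] / C with mid-ranks R and the
    tie correction C = 1 - sum(t^3 - t)/(N^3 - N). When every value is tied
    (C = 0) the statistic is 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    ranks = rankdata(values)
    return _h_from_ranks(ranks, codes, len(levels), _tie_correction(values))


def _tie_correction(values: np.ndarray) -> float:
    n = len(values)
    _, t = np.unique(values, return_counts=True)
    return 1.0 - float((t**3 - t).sum()) / float(n**3 - n) if n > 1 else 0.0


def _h_from_ranks(ranks: np.ndarray, codes: np.ndarray, k: int, C: float) -> float:
    n = len(ranks)
    sums = np.bincount(codes, weights=ranks, minlength=k)
    counts = np.bincount(codes, minlength=k)
    h = 12.0 / (n * (n + 1)) * float((sums**2 / counts).sum()) - 3.0 * (n + 1)
    if C <= 0:
        return 0.0
    return h / C


def permutation_test(
    values,
    cov: SampleCovariates,
    n_perm: int = 2000,
    seed: Optional[int] = None,
) -> AssociationResult:
    """Empirical Kruskal-Wallis test of ``values`` across ``cov.group``.

    The permutation scheme follows the design encoded in ``cov``: values are
    shuffled freely (plain), within strata (stratified), or as Freedman-Lane
    residuals re-added to the nuisance fit (adjusted). With no adjustment
    columns the adjusted scheme degenerates to the plain one permutation for
    permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    if len(values) != len(cov.sample_ids):
        raise ValueError("values length must match covariates")

    mask = cov.include if cov.include is not None else np.ones(len(values), bool)
    y = values[mask]
    groups = cov.group[mask]
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("fewer than 2 group levels after subsetting")
    k = len(levels)
    n = len(y)
    rng = np.random.default_rng(seed)
    variant = cov.variant

    if cov.adjust is not None and cov.adjust.shape[1] > 0:
        X = pd.get_dummies(cov.adjust.loc[mask].astype(str), drop_first=True)
        X = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
    else:
        # intercept-only fit: permuting residuals and re-adding the constant
        # is exactly a permutation of the values
        fitted = np.zeros(n)
        resid = y.copy()

    h_obs = _h_from_ranks(rankdata(y), codes, k, _tie_correction(y))

    if cov.strata is not None:
        strata = cov.strata[mask]
        strat_levels, strat_codes = np.unique(strata, return_inverse=True)
        strat_idx = [np.where(strat_codes == s)[0] for s in range(len(strat_levels))]
        for idx in strat_idx:
            if len(idx) < 2:
                raise ValueError("each stratum needs at least 2 samples")
    else:
        strat_idx = None

    exceed = 0
    for _ in range(n_perm):
        if strat_idx is not None:
            perm = np.arange(n)
            for idx in strat_idx:
                perm[idx] = idx[rng.permutation(len(idx))]
            y_star = y[perm]
        else:
            y_star = fitted + resid[rng.permutation(n)]
        h = _h_from_ranks(rankdata(y_star), codes, k, _tie_correction(y_star))
        if h >= h_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return AssociationResult(statistic=h_obs, p_empirical=p, n_perm=n_perm,
                             variant=variant, seed=seed)


@dataclass
class VariantSpec:
    """One analysis design applied to a covariate table.

    ``group`` names the column under test; ``strata``/``adjust``/``include``
    name optional columns of the covariate table.
    """

    name: str
    group: str
    strata: Optional[str] = None
    adjust: Sequence[str] = ()
    include: Optional[str] = None

    def bind(self, covariates: pd.DataFrame) -> SampleCovariates:
        return SampleCovariates(
            sample_ids=[str(s) for s in covariates.index],
            group=covariates[self.group].to_numpy(),
            strata=None if self.strata is None else covariates[self.strata].to_numpy(),
            adjust=None if not self.adjust else covariates[list(self.adjust)],
            include=None if self.include is None
            else covariates[self.include].astype(bool).to_numpy(),
        )


def run_panel(
    exposures: ExposureMatrix,
    covariates: pd.DataFrame,
    variants: Sequence[VariantSpec],
    n_perm: int = 2000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Run every requested design for every signature.

    Returns one row per signature x variant with the observed H and its
    empirical p. No multiplicity adjustment is applied. Sample ids must align
    exactly between the exposure matrix and the covariate table.
    """
    exp_ids = [str(s) for s in exposures.samples]
    cov_ids = [str(s) for s in covariates.index]
    missing = sorted(set(exp_ids) ^ set(cov_ids))
    if missing:
        raise ValueError(f"sample id mismatch between exposures and covariates: {missing}")
    covariates = covariates.loc[exp_ids]

    ss = np.random.SeedSequence(seed)
    rows = []
    for spec in variants:
        cov = spec.bind(covariates)
        for i, sig in enumerate(exposures.signatures):
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = permutation_test(exposures.H[i, :], cov, n_perm=n_perm, seed=sub_seed)
            rows.append(
                {"signature": sig, "variant": spec.name, "design": res.variant,
                 "H": res.statistic, "p_empirical": res.p_empirical,
                 "n_perm": res.n_perm, "seed": res.seed}
            )
    return pd.DataFrame(rows)
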