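"""IHC marker positivity, breast-cancer subtype assignment, and exact
contingency-table statistics.

Tumors are classified from immunohistochemistry into the four clinical
subtypes (luminal A: ER+/HER2-; luminal B: ER+/HER2+; HER2-enriched:
ER-/HER2+; triple-negative: ER-/PR-/HER2-), with triple-negative tumors
further split into basal / non-basal by EGFR and CK5/6 staining.
Associations between categorical variables are tested with Fisher's exact
test (2x2) or its Freeman-Halton r x c generalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IHCRecord",
    "SubtypeCall",
    "ContingencyTable",
    "PositivityThresholds",
    "RxCResult",
    "SUBTYPES",
    "call_positivity",
    "assign_subtype",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "tabulate",
    "read_ihc_tsv",
]

SUBTYPES = ("LuminalA", "LuminalB", "HER2enriched", "TripleNegative", "Undetermined")
HER2_CATEGORIES = ("negative", "equivocal", "positive")

#: Relative tolerance used when comparing table probabilities to the observed
#: one, guarding against float ties in the "probability at most observed" rule.
P_REL_TOL = 1e-7


@dataclass
class PositivityThresholds:
    """Staining-percentage cutoffs; positivity is a strict inequality.

    Defaults follow the St Gallen convention: ER/PR positive above 1% stained
    cells, Ki67 positive above 14%.
    """

    er_pct: float = 1.0
    pr_pct: float = 1.0
    ki67_pct: float = 14.0


@dataclass
class IHCRecord:
    """Immunohistochemistry measurements for one case."""

    case_id: str
    er_pct: float
    pr_pct: float
    her2: str
    ki67_pct: Optional[float] = None
    egfr_pos: Optional[bool] = None
    ck56_pos: Optional[bool] = None
    p53_stain: Optional[str] = None
    fish_confirmed: bool = False

    def __post_init__(self) -> None:
        for name in ("er_pct", "pr_pct", "ki67_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v!r} outside [0, 100] for case {self.case_id}")
        if self.her2 not in HER2_CATEGORIES:
            raise ValueError(
                f"her2={self.her2!r} not in {HER2_CATEGORIES} for case {self.case_id}"
            )


@dataclass
class SubtypeCall:
    """Subtype label derived from an :class:`IHCRecord`.

    ``basal`` is only meaningful for triple-negative tumors; elsewhere it is
    ``"not-applicable"``.
    """

    case_id: str
    subtype: str
    basal: str = "not-applicable"
    ki67_positive: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.subtype == "TripleNegative":
            if self.basal not in ("basal", "non-basal"):
                raise ValueError("triple-negative calls need basal or non-basal")
        elif self.basal != "not-applicable":
            raise ValueError("basal status only applies to triple-negative tumors")


def call_positivity(
    record: IHCRecord, thresholds: PositivityThresholds | None = None
) -> dict[str, Optional[bool]]:
    """Per-marker positivity booleans (``None`` where the marker is missing)."""
    t = thresholds or PositivityThresholds()
    return {
        "er": record.er_pct > t.er_pct,
        "pr": record.pr_pct > t.pr_pct,
        "ki67": None if record.ki67_pct is None else record.ki67_pct > t.ki67_pct,
    }


def assign_subtype(
    record: IHCRecord, thresholds: PositivityThresholds | None = None
) -> SubtypeCall:
    """Assign the clinical subtype from ER/PR/HER2, with basal sub-typing of
    triple-negative tumors by EGFR and/or CK5/6.

    An equivocal HER2 result without confirmatory FISH cannot be classified
    and yields ``Undetermined``, as does the leftover ER-/PR+/HER2- pattern.
    """
    pos = call_positivity(record, thresholds)
    ki67 = pos["ki67"]

    if record.her2 == "equivocal" and not record.fish_confirmed:
        return SubtypeCall(record.case_id, "Undetermined", ki67_positive=ki67)
    # a FISH-confirmed equivocal result is treated as resolved-positive
    her2_pos = record.her2 == "positive" or (
        record.her2 == "equivocal" and record.fish_confirmed
    )

    if pos["er"]:
        subtype = "LuminalB" if her2_pos else "LuminalA"
    elif her2_pos:
        subtype = "HER2enriched"
    elif not pos["pr"]:
        subtype = "TripleNegative"
    else:  # ER-/PR+/HER2-
        subtype = "Undetermined"

    if subtype == "TripleNegative":
        basal = "basal" if (record.egfr_pos or record.ck56_pos) else "non-basal"
        return SubtypeCall(record.case_id, subtype, basal=basal, ki67_positive=ki67)
    return SubtypeCall(record.case_id, subtype, ki67_positive=ki67)


@dataclass
class ContingencyTable:
    row_labels: Sequence[str]
    col_labels: Sequence[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        r, c = self.counts.shape
        if r < 1 or c < 1:
            raise ValueError("empty table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("labels do not match table shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return np.asarray(table, dtype=np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided by the probability rule: the p-value sums the hypergeometric
    probabilities of all margin-fixed tables no more probable than the
    observed one. A degenerate table (zero row or column margin) has p = 1.
    """
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


@dataclass
class RxCResult:
    """Outcome of the r x c exact/Monte-Carlo test."""

    p: float
    method: str  # "enumeration" or "monte-carlo"
    n_tables: Optional[int] = None  # tables enumerated (enumeration path)
    n_reps: Optional[int] = None  # samples drawn (MC path)
    seed: Optional[int] = None


def fisher_exact_rxc(
    table,
    mc_reps: Optional[int] = None,
    seed: Optional[int] = None,
    enumeration_cap: int = 300,
) -> RxCResult:
    """Freeman-Halton exact test for an r x c table of counts.

    Enumerates every table with the observed margins when the grand total is
    at most ``enumeration_cap`` and sums the probabilities of tables no more
    probable than the observed one. Larger tables fall back to a Monte-Carlo
    estimate over ``mc_reps`` margin-preserving samples (Patefield sampling);
    requesting a large table without ``mc_reps`` is an error.
    """
    counts = _as_counts(table)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if counts.shape == (2, 2):
        return RxCResult(p=fisher_exact_2x2(counts), method="enumeration")

    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    keep_r, keep_c = rows > 0, cols > 0
    counts = counts[np.ix_(keep_r, keep_c)]
    rows, cols = rows[keep_r], cols[keep_c]
    if counts.size == 0 or min(counts.shape) < 2:
        return RxCResult(p=1.0, method="enumeration", n_tables=1)

    lg = math.lgamma
    log_const = sum(lg(r + 1) for r in rows) + sum(lg(c + 1) for c in cols) - lg(
        rows.sum() + 1
    )

    def logprob(t: np.ndarray) -> float:
        return log_const - math.fsum(lg(x + 1) for x in t.flat)

    lp_obs = logprob(counts)
    cutoff = lp_obs + math.log1p(P_REL_TOL)
    total = int(rows.sum())

    if total <= enumeration_cap:
        n_rows = len(rows)
        acc = 0.0
        n_tables = 0

        def recurse(i: int, col_rem: np.ndarray, lp_partial: float) -> None:
            nonlocal acc, n_tables
            if i == n_rows - 1:
                row = col_rem
                if (row <= rows[i]).all() and row.sum() == rows[i]:
                    lp = lp_partial - math.fsum(lg(x + 1) for x in row)
                    n_tables += 1
                    if lp <= cutoff:
                        acc += math.exp(lp)
                return
            for row in _compositions(int(rows[i]), col_rem):
                lp = lp_partial - math.fsum(lg(x + 1) for x in row)
                recurse(i + 1, col_rem - row, lp)

        recurse(0, cols.copy(), log_const)
        return RxCResult(p=min(acc, 1.0), method="enumeration", n_tables=n_tables)

    if mc_reps is None:
        raise ValueError(
            f"table total {total} exceeds enumeration cap {enumeration_cap}; "
            "set mc_reps for a Monte-Carlo estimate"
        )
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols, seed=rng)
    draws = sampler.rvs(mc_reps)  # (reps, r, c)
    lgs = np.vectorize(lg)
    lps = log_const - lgs(draws + 1.0).sum(axis=(1, 2))
    hits = int((lps <= cutoff).sum())
    p = (1 + hits) / (1 + mc_reps)
    return RxCResult(p=p, method="monte-carlo", n_reps=mc_reps, seed=seed)


def _compositions(total: int, caps: np.ndarray):
    """All ways to write ``total`` as a vector bounded above by ``caps``."""
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield np.array([total], dtype=np.int64)
        return
    for first in range(0, min(total, int(caps[0])) + 1):
        for rest in _compositions(total - first, caps[1:]):
            yield np.concatenate(([first], rest))


def tabulate(
    records: Iterable[Mapping] | pd.DataFrame,
    row_var: str,
    col_var: str,
) -> tuple[ContingencyTable, int]:
    """Cross-tabulate two categorical variables over a set of calls.

    Records may be dataclass instances, dicts, or a DataFrame. Rows with a
    missing value in either variable are dropped; the dropped count is
    returned alongside the table.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if isinstance(r, Mapping):
                rows.append(dict(r))
            else:
                rows.append(vars(r))
        df = pd.DataFrame(rows)
    for v in (row_var, col_var):
        if v not in df.columns:
            raise KeyError(f"variable {v!r} not present")
    sub = df[[row_var, col_var]]
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    if kept.empty:
        raise ValueError("no records left after dropping missing values")
    ct = pd.crosstab(kept[row_var], kept[col_var])
    return (
        ContingencyTable(
            row_labels=[str(x) for x in ct.index],
            col_labels=[str(x) for x in ct.columns],
            counts=ct.to_numpy(),
        ),
        n_dropped,
    )


def read_ihc_tsv(path) -> list[IHCRecord]:
    """Read a tab-separated IHC table (one row per case, empty cell = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str})
    records = []
    for _, row in df.iterrows():
        def opt(name, cast=float):
            v = row.get(name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return cast(v)

        records.append(
            IHCRecord(
                case_id=str(row["case_id"]),
                er_pct=float(row["er_pct"]),
                pr_pct=float(row["pr_pct"]),
                her2=str(row["her2"]),
                ki67_pct=opt("ki67_pct"),
                egfr_pos=opt("egfr_pos", lambda v: bool(int(v))),
                ck56_pos=opt("ck56_pos", lambda v: bool(int(v))),
                p53_stain=opt("p53_stain", str),
                fish_confirmed=bool(int(row.get("fish_confirmed", 0) or 0)),
            )
        )
    return records
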