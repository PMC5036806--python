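"""Two-locus multifactor dimensionality reduction (MDR) statistic.

MDR turns a two-locus genotype table into a single binary predictor: the
quantitative trait is first dichotomised into case/control, each genotype
cell is labelled high- or low-risk by comparing its case:control ratio with
the table-wide ratio, the nine cells are pooled into a 2x2 (risk x status)
table, and association is scored with an uncorrected Pearson chi-square on
1 degree of freedom.  A 10x10-fold cross-validated mean chi-square measures
how well the learned high/low partition generalises.

The dichotomisation rule is a reconstruction choice: a per-environment
median split (ties to control) is the default, a mean split is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simdata import PhenotypeSet, RILPopulation

__all__ = [
    "BinaryPhenotype",
    "TwoLocusTable",
    "RiskAssignment",
    "PairStatistic",
    "DegeneratePhenotypeError",
    "SampleSizeError",
    "EmptyTableError",
    "ZeroMarginError",
    "binarize_phenotype",
    "build_two_locus_table",
    "classify_cells",
    "pool_counts",
    "pooled_chi_square",
    "cv_mean_chi_square",
]

HIGH, LOW, EMPTY = 1, 0, -1


class DegeneratePhenotypeError(ValueError):
    """All trait values identical: no case/control split exists."""


class SampleSizeError(ValueError):
    """Too few lines for the requested operation."""


class EmptyTableError(ValueError):
    """A two-locus table with no occupied cell."""


class ZeroMarginError(ValueError):
    """Case or control margin empty: risk threshold undefined."""


@dataclass(frozen=True)
class BinaryPhenotype:
    """Case/control labels derived from a quantitative trait."""

    is_case: dict[str, bool]
    rule: str = "median"

    @property
    def n_case(self) -> int:
        return sum(self.is_case.values())

    @property
    def n_control(self) -> int:
        return len(self.is_case) - self.n_case


@dataclass(frozen=True)
class TwoLocusTable:
    """Case/control counts over the 3x3 genotype-code grid of a marker pair.

    Rows/columns index genotype codes 0, 1, 2 at marker A and B; lines with
    a missing call at either marker are tallied in ``excluded``.
    """

    cases: np.ndarray  # (3, 3) int64
    controls: np.ndarray  # (3, 3) int64
    excluded: int = 0

    @property
    def totals(self) -> np.ndarray:
        return self.cases + self.controls

    @property
    def n_case(self) -> int:
        return int(self.cases.sum())

    @property
    def n_control(self) -> int:
        return int(self.controls.sum())


@dataclass(frozen=True)
class RiskAssignment:
    """High/low/empty label per genotype cell plus the threshold used."""

    status: np.ndarray  # (3, 3) in {HIGH, LOW, EMPTY}
    threshold: float


@dataclass(frozen=True)
class PairStatistic:
    """Pooled 2x2 chi-square for one marker pair."""

    chi_square: float
    p_value: float
    cv_mean_chi_square: float | None = None
    defined: bool = True


def binarize_phenotype(pheno: PhenotypeSet, rule: str = "median") -> BinaryPhenotype:
    """Dichotomise trait values around the median (default) or mean.

    Values strictly above the centre become cases; values at or below it
    (ties included) become controls.  Location-shifting every value leaves
    the labels unchanged.
    """
    if rule not in ("median", "mean"):
        raise ValueError(f"unknown binarization rule {rule!r}")
    if len(pheno) < 4:
        raise SampleSizeError(f"need >= 4 phenotyped lines, got {len(pheno)}")
    vals = np.fromiter(pheno.values.values(), dtype=np.float64, count=len(pheno))
    if np.ptp(vals) == 0:
        raise DegeneratePhenotypeError(f"all values identical in {pheno.env_id}")
    centre = float(np.median(vals)) if rule == "median" else float(vals.mean())
    labels = {line: v > centre for line, v in pheno.values.items()}
    if not any(labels.values()) or all(labels.values()):
        raise DegeneratePhenotypeError(f"degenerate split in {pheno.env_id}")
    return BinaryPhenotype(labels, rule)


def build_two_locus_table(
    pop: RILPopulation,
    marker_a: str,
    marker_b: str,
    labels: BinaryPhenotype,
    line_ids: list[str] | None = None,
) -> TwoLocusTable:
    """Tally labelled lines into the 3x3 genotype grid of a marker pair.

    Only labelled lines are counted; a line missing (-1) at either marker
    increments ``excluded`` instead of a cell.
    """
    if marker_a == marker_b:
        raise ValueError("the two markers must be distinct")
    ia, ib = pop.marker_index(marker_a), pop.marker_index(marker_b)
    if line_ids is None:
        line_ids = [l for l in pop.line_ids if l in labels.is_case]
    rows = {l: i for i, l in enumerate(pop.line_ids)}
    idx = np.array([rows[l] for l in line_ids], dtype=np.intp)
    ga, gb = pop.genotypes[idx, ia], pop.genotypes[idx, ib]
    case = np.array([labels.is_case[l] for l in line_ids], dtype=bool)
    valid = (ga >= 0) & (gb >= 0)
    cell = ga[valid].astype(np.int64) * 3 + gb[valid]
    cases = np.bincount(cell[case[valid]], minlength=9).reshape(3, 3)
    controls = np.bincount(cell[~case[valid]], minlength=9).reshape(3, 3)
    return TwoLocusTable(cases, controls, excluded=int((~valid).sum()))


def classify_cells(table: TwoLocusTable) -> RiskAssignment:
    """Label each occupied cell high- or low-risk against the table ratio.

    The threshold T is the table-wide case:control ratio; a cell is
    high-risk iff its own ratio is >= T, with a case-only cell (zero
    controls) always high.  Ties resolve to high risk.
    """
    totals = table.totals
    if totals.sum() == 0:
        raise EmptyTableError("no occupied genotype cell")
    n_case, n_control = table.n_case, table.n_control
    if n_case == 0 or n_control == 0:
        raise ZeroMarginError("need both cases and controls to set the risk threshold")
    # cases/controls >= n_case/n_control, cross-multiplied to dodge 0-division
    high = table.cases * n_control >= table.controls * n_case
    status = np.where(totals > 0, np.where(high, HIGH, LOW), EMPTY)
    return RiskAssignment(status, n_case / n_control)


def pool_counts(table: TwoLocusTable, risk: RiskAssignment) -> np.ndarray:
    """Pool a table into the 2x2 [[high-case, high-ctrl], [low-case, low-ctrl]].

    Cells the risk model never saw (EMPTY in the assignment) pool as low
    risk, so a model learned on training folds applies to unseen cells.
    """
    high = risk.status == HIGH
    hc = int(table.cases[high].sum())
    hn = int(table.controls[high].sum())
    return np.array([[hc, hn], [table.n_case - hc, table.n_control - hn]], dtype=np.int64)


def pooled_chi_square(table: TwoLocusTable, risk: RiskAssignment) -> PairStatistic:
    """Pearson chi-square (1 df, no continuity correction) of the pooled 2x2.

    A zero margin leaves the statistic undefined; such pairs are reported
    with p = 1 and ``defined=False`` so callers can skip them.
    """
    pooled = pool_counts(table, risk)
    (a, b), (c, d) = pooled
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return PairStatistic(0.0, 1.0, defined=False)
    chi = n * (a * d - b * c) ** 2 / denom
    return PairStatistic(float(chi), float(stats.chi2.sf(chi, 1)))


def _stratified_folds(
    case_ids: list[str], ctrl_ids: list[str], k: int, rng: np.random.Generator
) -> list[list[str]]:
    """Shuffle each class and deal lines round-robin into k folds."""
    folds: list[list[str]] = [[] for _ in range(k)]
    for ids in (case_ids, ctrl_ids):
        order = rng.permutation(len(ids))
        for j, idx in enumerate(order):
            folds[j % k].append(ids[idx])
    return folds


def cv_mean_chi_square(
    pop: RILPopulation,
    marker_a: str,
    marker_b: str,
    labels: BinaryPhenotype,
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
) -> float:
    """Mean out-of-fold chi-square over ``reps`` rounds of stratified k-fold CV.

    Per repetition the lines are dealt into k label-stratified folds; each
    held-out fold is pooled into high/low risk using the partition learned
    on the other k-1 folds, the held-out 2x2 counts are accumulated across
    the k folds (every line predicted exactly once, out of fold), and one
    Pearson chi-square is computed from the aggregate.  This keeps the CV
    statistic on the same scale as the full-data chi-square: a perfectly
    generalising pair retains its full statistic, while a partition that
    merely overfits the training folds collapses towards the null mean of 1.
    Folds whose training table yields no risk model contribute their lines
    to the low-risk row; a repetition with a zero margin contributes 0.
    Deterministic for a given ``seed``.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    present = [l for l in pop.line_ids if l in labels.is_case]
    if len(present) < k:
        raise SampleSizeError(f"need >= {k} labelled lines, got {len(present)}")
    case_ids = [l for l in present if labels.is_case[l]]
    ctrl_ids = [l for l in present if not labels.is_case[l]]
    rng = np.random.default_rng(seed)
    all_low = RiskAssignment(np.full((3, 3), LOW), threshold=np.nan)
    values: list[float] = []
    for _ in range(reps):
        folds = _stratified_folds(case_ids, ctrl_ids, k, rng)
        pooled = np.zeros((2, 2), dtype=np.int64)
        for f in range(k):
            test = folds[f]
            train = [l for g in range(k) if g != f for l in folds[g]]
            try:
                risk = classify_cells(build_two_locus_table(pop, marker_a, marker_b, labels, train))
            except (EmptyTableError, ZeroMarginError):
                risk = all_low
            test_table = build_two_locus_table(pop, marker_a, marker_b, labels, test)
            pooled += pool_counts(test_table, risk)
        (a, b), (c, d) = pooled
        n = pooled.sum()
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        values.append(float(n * (a * d - b * c) ** 2 / denom) if denom else 0.0)
    return float(np.mean(values))
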