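"""Per-pair epistatic values and contribution rates by two-way ANOVA.

For each stable pair and each environment in which it was scan-significant,
the quantitative trait is modelled as a 2x2 factorial over the two
homozygous genotype classes (heterozygous and missing calls are dropped —
inbred lines are essentially homozygous).  The interaction is tested at an
uncorrected p < 0.01; the epistatic value is the interaction contrast of
the four unweighted cell means

    e = (m_AA,BB + m_aa,bb - m_AA,bb - m_aa,BB) / 4

(the two-locus physiological-epistasis measure, equal to the effect-coded
interaction regression coefficient in a balanced design), and the
contribution rate is the interaction share of total phenotypic variation,
SS_AB / SS_total.

Unbalanced cell counts are handled by partial (Type III-equivalent) sums of
squares — each term's SS is the residual-SS increase when that term is
dropped from the full model — so the decomposition does not depend on term
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simdata import PhenotypeSet, RILPopulation
from .stability import StabilityRecord

__all__ = [
    "AnovaResult",
    "EpistasisRecord",
    "RankDeficiencyError",
    "two_way_anova",
    "epistatic_value",
    "contribution_rate",
    "epistasis_report",
    "records_to_frame",
]


class RankDeficiencyError(ValueError):
    """The 2x2 factorial cannot be estimated (empty factor level or cell)."""


@dataclass(frozen=True)
class AnovaResult:
    """Sums of squares and interaction test for one pair x environment."""

    ss_a: float
    ss_b: float
    ss_ab: float
    ss_error: float
    ss_total: float
    df_ab: int
    df_error: int
    f_ab: float
    p_ab: float
    cell_means: dict[tuple[int, int], float]  # keyed by genotype codes (0/2, 0/2)
    cell_counts: dict[tuple[int, int], int]


@dataclass(frozen=True)
class EpistasisRecord:
    marker_a: str
    marker_b: str
    env_id: str
    epistatic_value: float | None
    contribution_rate: float | None
    p_ab: float | None
    significant: bool
    reason: str | None = None  # set when the ANOVA could not be run


def _design(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(xa), xa, xb, xa * xb])


def two_way_anova(
    pheno: PhenotypeSet, pop: RILPopulation, marker_a: str, marker_b: str
) -> AnovaResult:
    """2x2 factorial ANOVA of the trait on two homozygous marker genotypes.

    Uses only lines phenotyped and homozygous (codes 0/2) at both markers.
    Requires all four genotype cells occupied and at least one residual
    degree of freedom, else raises :class:`RankDeficiencyError`.
    """
    if marker_a == marker_b:
        raise ValueError("the two markers must be distinct")
    ia, ib = pop.marker_index(marker_a), pop.marker_index(marker_b)
    rows = {l: i for i, l in enumerate(pop.line_ids)}
    lines = [l for l in pop.line_ids if l in pheno.values]
    idx = np.array([rows[l] for l in lines], dtype=np.intp)
    ga, gb = pop.genotypes[idx, ia], pop.genotypes[idx, ib]
    keep = np.isin(ga, (0, 2)) & np.isin(gb, (0, 2))
    ga, gb = ga[keep], gb[keep]
    y = np.array([pheno.values[l] for l in lines], dtype=np.float64)[keep]

    cell_means: dict[tuple[int, int], float] = {}
    cell_counts: dict[tuple[int, int], int] = {}
    for a in (0, 2):
        for b in (0, 2):
            mask = (ga == a) & (gb == b)
            cell_counts[(a, b)] = int(mask.sum())
            if mask.any():
                cell_means[(a, b)] = float(y[mask].mean())
    if len(cell_means) < 4:
        raise RankDeficiencyError(
            f"pair ({marker_a}, {marker_b}) in {pheno.env_id}: empty genotype cell"
        )
    n = len(y)
    if n - 4 < 1:
        raise RankDeficiencyError(
            f"pair ({marker_a}, {marker_b}) in {pheno.env_id}: no residual degrees of freedom"
        )

    xa = ga.astype(np.float64) - 1.0  # {-1, +1}
    xb = gb.astype(np.float64) - 1.0
    X = _design(xa, xb)
    full = sm.OLS(y, X).fit()
    ss_error = float(full.ssr)
    ss_total = float(np.sum((y - y.mean()) ** 2))

    def drop_ss(col: int) -> float:
        reduced = sm.OLS(y, np.delete(X, col, axis=1)).fit()
        return float(reduced.ssr) - ss_error

    ss_a, ss_b, ss_ab = drop_ss(1), drop_ss(2), drop_ss(3)
    df_error = n - 4
    f_ab = (ss_ab / 1.0) / (ss_error / df_error) if ss_error > 0 else np.inf
    p_ab = float(stats.f.sf(f_ab, 1, df_error)) if np.isfinite(f_ab) else 0.0
    return AnovaResult(
        ss_a=max(ss_a, 0.0),
        ss_b=max(ss_b, 0.0),
        ss_ab=max(ss_ab, 0.0),
        ss_error=ss_error,
        ss_total=ss_total,
        df_ab=1,
        df_error=df_error,
        f_ab=float(f_ab),
        p_ab=p_ab,
        cell_means=cell_means,
        cell_counts=cell_counts,
    )


def epistatic_value(cell_means: Sequence[float]) -> float:
    """Interaction contrast of the four homozygous cell means.

    ``cell_means`` is (m00, m02, m20, m22) in genotype-code order; returns
    (m00 + m22 - m02 - m20) / 4 in trait units.
    """
    m00, m02, m20, m22 = (float(v) for v in cell_means)
    return (m00 + m22 - m02 - m20) / 4.0


def contribution_rate(anova: AnovaResult) -> float:
    """Interaction share of phenotypic variation, SS_AB / SS_total."""
    if anova.ss_total <= 0:
        raise ValueError("degenerate phenotype: zero total sum of squares")
    return min(anova.ss_ab / anova.ss_total, 1.0)


def epistasis_report(
    stable: Sequence[StabilityRecord],
    phenos: Sequence[PhenotypeSet],
    pop: RILPopulation,
    alpha2: float = 0.01,
) -> tuple[list[EpistasisRecord], dict[int, int]]:
    """ANOVA every stable pair in each environment where it was significant.

    Returns one record per pair x environment (NS records kept, with a
    reason when the model could not be fitted) and a histogram mapping
    number-of-significant-environments -> pair count over pairs with at
    least one significant environment.
    """
    if not stable:
        raise ValueError("no stable pairs to analyse")
    by_env = {p.env_id: p for p in phenos}
    records: list[EpistasisRecord] = []
    sig_envs: dict[tuple[str, str], int] = {}
    for rec in stable:
        for env in rec.env_ids:
            if env not in by_env:
                records.append(
                    EpistasisRecord(
                        rec.marker_a, rec.marker_b, env, None, None, None, False,
                        reason="phenotype set missing",
                    )
                )
                continue
            try:
                anova = two_way_anova(by_env[env], pop, rec.marker_a, rec.marker_b)
            except RankDeficiencyError as exc:
                records.append(
                    EpistasisRecord(
                        rec.marker_a, rec.marker_b, env, None, None, None, False,
                        reason=str(exc),
                    )
                )
                continue
            means = anova.cell_means
            e = epistatic_value(
                (means[(0, 0)], means[(0, 2)], means[(2, 0)], means[(2, 2)])
            )
            rate = contribution_rate(anova)
            significant = anova.p_ab < alpha2
            if significant:
                key = (rec.marker_a, rec.marker_b)
                sig_envs[key] = sig_envs.get(key, 0) + 1
            records.append(
                EpistasisRecord(
                    rec.marker_a, rec.marker_b, env, e, rate, anova.p_ab, significant
                )
            )
    histogram: dict[int, int] = {}
    for count in sig_envs.values():
        histogram[count] = histogram.get(count, 0) + 1
    return records, dict(sorted(histogram.items(), reverse=True))


def records_to_frame(records: Sequence[EpistasisRecord]) -> pd.DataFrame:
    """Tabulate records with the NS convention of the published supplement."""
    rows = []
    for r in records:
        rows.append(
            {
                "marker_a": r.marker_a,
                "marker_b": r.marker_b,
                "env_id": r.env_id,
                "epistatic_value": r.epistatic_value,
                "abs_epistatic_value": None if r.epistatic_value is None else abs(r.epistatic_value),
                "contribution_rate": r.contribution_rate,
                "p_value": r.p_ab,
                "flag": "SIG" if r.significant else "NS",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_a",
            "marker_b",
            "env_id",
            "epistatic_value",
            "abs_epistatic_value",
            "contribution_rate",
            "p_value",
            "flag",
        ],
    )
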