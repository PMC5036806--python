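"""Synthetic biparental RIL populations with known trait architecture.

Simulates a recombinant-inbred-line (RIL) population derived by repeated
selfing from a cross of two fully homozygous parents, genotyped on a dense
genetic map, together with multi-environment quantitative phenotypes driven
by a planted architecture of additive and pairwise epistatic marker effects.
Because every effect is planted, downstream scanning and estimation stages
can be validated by parameter recovery.

Genotype codes follow the two-parent convention used throughout the package:
``0`` = parent-A homozygote, ``2`` = parent-B homozygote, ``1`` = residual
heterozygote, ``-1`` = missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LinkageMap",
    "RILPopulation",
    "TraitArchitecture",
    "PhenotypeSet",
    "haldane_r",
    "ril_expansion",
    "default_map",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
]

VALID_CODES = (-1, 0, 1, 2)


class ConfigurationError(ValueError):
    """An architecture or config references entities that do not exist."""


@dataclass(frozen=True)
class LinkageMap:
    """Ordered genetic map: marker names, linkage groups, cM positions.

    Markers must be sorted by linkage group and, within each group, by
    non-decreasing centimorgan position.
    """

    marker_ids: tuple[str, ...]
    groups: np.ndarray  # int, 1..G
    positions: np.ndarray  # float cM, >= 0

    def __post_init__(self) -> None:
        groups = np.asarray(self.groups, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "positions", positions)
        m = len(self.marker_ids)
        if m == 0:
            raise ValueError("map must contain at least one marker")
        if groups.shape != (m,) or positions.shape != (m,):
            raise ValueError("marker_ids, groups and positions must align")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids must be unique")
        if (positions < 0).any():
            raise ValueError("cM positions must be non-negative")
        if groups.min() < 1:
            raise ValueError("linkage groups are numbered from 1")
        for g in np.unique(groups):
            pos = positions[groups == g]
            if (np.diff(pos) < 0).any():
                raise ValueError(f"positions not sorted within linkage group {g}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_groups(self) -> int:
        return int(len(np.unique(self.groups)))

    @property
    def length_cm(self) -> float:
        """Total map length: sum of per-group spans (max - min position)."""
        total = 0.0
        for g in np.unique(self.groups):
            pos = self.positions[self.groups == g]
            total += float(pos.max() - pos.min())
        return total

    @property
    def mean_spacing_cm(self) -> float:
        """Average adjacent-marker distance: length over (m - G) gaps."""
        gaps = self.n_markers - self.n_groups
        if gaps == 0:
            return 0.0
        return self.length_cm / gaps

    def index_of(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not on the map") from None


@dataclass(frozen=True)
class RILPopulation:
    """Genotype matrix (lines x markers) for an inbred biparental population."""

    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    genotypes: np.ndarray  # (n, m) int8, codes in {-1, 0, 1, 2}

    def __post_init__(self) -> None:
        geno = np.asarray(self.genotypes, dtype=np.int8)
        object.__setattr__(self, "genotypes", geno)
        n, m = geno.shape
        if n != len(self.line_ids) or m != len(self.marker_ids):
            raise ValueError("genotype matrix does not match line/marker ids")
        if len(set(self.line_ids)) != n:
            raise ValueError("line ids must be unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids must be unique")
        if not np.isin(geno, VALID_CODES).all():
            bad = sorted(set(np.unique(geno)) - set(VALID_CODES))
            raise ValueError(f"invalid genotype codes {bad}; allowed {VALID_CODES}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not genotyped") from None


@dataclass
class TraitArchitecture:
    """Planted generative model for the quantitative trait.

    The phenotype of line *l* in environment *e* is

        y_le = mu + sum_i a_i x_il + sum_(i,j) w_ij x_il x_jl + s_e + eps_le

    with effect coding x = genotype - 1 in {-1, +1} for the two homozygote
    classes; heterozygous or missing calls contribute 0 to any effect term.
    Residual noise is Gaussian, independent per line x environment, with a
    global ``residual_sd`` optionally overridden per environment.
    """

    grand_mean: float
    additive_effects: Sequence[tuple[str, float]] = ()
    epistatic_pairs: Sequence[tuple[str, str, float]] = ()
    environment_effects: Sequence[tuple[str, float]] = ()
    residual_sd: float = 0.5
    env_residual_sd: Mapping[str, float] | None = None
    het_rate: float = 0.002
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        for rate, name in ((self.het_rate, "het_rate"), (self.missing_rate, "missing_rate")):
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must lie in [0, 1)")

    def shift_of(self, env_id: str) -> float:
        return dict(self.environment_effects).get(env_id, 0.0)

    def sd_of(self, env_id: str) -> float:
        if self.env_residual_sd and env_id in self.env_residual_sd:
            return float(self.env_residual_sd[env_id])
        return float(self.residual_sd)


@dataclass(frozen=True)
class PhenotypeSet:
    """Trait values (e.g. % seed oil) for one environment (year x location)."""

    env_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        arr = np.fromiter(self.values.values(), dtype=np.float64, count=len(self.values))
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite phenotype values in environment {self.env_id}")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self, line_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.values[l] for l in line_ids], dtype=np.float64)


def haldane_r(d: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: cM distance -> single-meiosis recombination fraction.

    r = 0.5 * (1 - exp(-2 d / 100)); assumes no crossover interference.
    """
    d = np.asarray(d, dtype=np.float64)
    if (d < 0).any():
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def ril_expansion(r: float | np.ndarray) -> float | np.ndarray:
    """Expected proportion of recombinant lines between two loci in a selfed RIL.

    Repeated selfing accumulates recombination: R = 2r / (1 + 2r), which
    maps the single-meiosis fraction r in [0, 0.5] onto [0, 0.5].
    """
    r = np.asarray(r, dtype=np.float64)
    if ((r < 0) | (r > 0.5)).any():
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


def default_map(
    n_markers: int = 5308,
    n_groups: int = 20,
    length_cm: float = 2294.433,
    prefix: str = "Mark",
) -> LinkageMap:
    """Evenly spaced map with the geometry of a dense soybean genetic map.

    Defaults mirror a published high-density SLAF-seq map: 5,308 markers on
    20 linkage groups spanning 2294.433 cM (0.43 cM mean spacing).  Markers
    are distributed as evenly as possible across groups and spaced uniformly
    so the per-group spans sum exactly to ``length_cm``.
    """
    if n_markers < n_groups:
        raise ValueError("need at least one marker per linkage group")
    gaps = n_markers - n_groups
    spacing = length_cm / gaps if gaps else 0.0
    base, extra = divmod(n_markers, n_groups)
    ids: list[str] = []
    groups: list[int] = []
    positions: list[float] = []
    k = 0
    for g in range(1, n_groups + 1):
        size = base + (1 if g <= extra else 0)
        for j in range(size):
            ids.append(f"{prefix}{k:05d}")
            groups.append(g)
            positions.append(j * spacing)
            k += 1
    return LinkageMap(tuple(ids), np.array(groups), np.array(positions))


def simulate_ril_genotypes(
    linkage_map: LinkageMap,
    n: int,
    seed: int,
    het_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> RILPopulation:
    """Draw ``n`` RIL genotypes along the map.

    Each line is an independent two-state Markov chain per linkage group:
    the first marker is parent A or parent B with probability 1/2, and each
    subsequent marker switches parent with probability
    ``ril_expansion(haldane_r(delta_cM))``.  Chains are independent across
    linkage groups (free recombination between chromosomes).  Residual
    heterozygosity and missingness are then overlaid i.i.d. per entry.
    Deterministic for a given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least two lines")
    for rate, name in ((het_rate, "het_rate"), (missing_rate, "missing_rate")):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    m = linkage_map.n_markers
    geno = np.empty((n, m), dtype=np.int8)
    for g in np.unique(linkage_map.groups):
        idx = np.flatnonzero(linkage_map.groups == g)
        pos = linkage_map.positions[idx]
        switch_p = ril_expansion(haldane_r(np.diff(pos)))
        first = rng.random((n, 1)) < 0.5
        if len(idx) > 1:
            switches = rng.random((n, len(idx) - 1)) < switch_p
            state = np.logical_xor.accumulate(np.hstack([first, switches]), axis=1)
        else:
            state = first
        geno[:, idx] = state.astype(np.int8) * 2
    if het_rate > 0:
        geno[rng.random((n, m)) < het_rate] = 1
    if missing_rate > 0:
        geno[rng.random((n, m)) < missing_rate] = -1
    line_ids = tuple(f"RIL{i + 1:03d}" for i in range(n))
    return RILPopulation(line_ids, linkage_map.marker_ids, geno)


def _effect_coding(geno: np.ndarray) -> np.ndarray:
    """Map codes to x in {-1, +1} for homozygotes, 0 for het/missing."""
    x = geno.astype(np.float64) - 1.0
    x[(geno != 0) & (geno != 2)] = 0.0
    return x


def simulate_phenotypes(
    pop: RILPopulation,
    arch: TraitArchitecture,
    env_ids: Sequence[str],
    seed: int,
) -> list[PhenotypeSet]:
    """Evaluate the planted trait model on the population in each environment.

    Deterministic for a given ``seed``; the residual stream is drawn
    environment by environment in the order of ``env_ids``.
    """
    if not env_ids:
        raise ValueError("env_ids must be non-empty")
    known = set(pop.marker_ids)
    for marker, _ in arch.additive_effects:
        if marker not in known:
            raise ConfigurationError(f"additive-effect marker {marker!r} not genotyped")
    for ma, mb, _ in arch.epistatic_pairs:
        for marker in (ma, mb):
            if marker not in known:
                raise ConfigurationError(f"epistatic-pair marker {marker!r} not genotyped")
    x = _effect_coding(pop.genotypes)
    genetic = np.zeros(pop.n_lines)
    for marker, a in arch.additive_effects:
        genetic += a * x[:, pop.marker_index(marker)]
    for ma, mb, w in arch.epistatic_pairs:
        genetic += w * x[:, pop.marker_index(ma)] * x[:, pop.marker_index(mb)]
    rng = np.random.default_rng(seed)
    out: list[PhenotypeSet] = []
    for env in env_ids:
        sd = arch.sd_of(env)
        eps = rng.normal(0.0, sd, pop.n_lines) if sd > 0 else np.zeros(pop.n_lines)
        y = arch.grand_mean + genetic + arch.shift_of(env) + eps
        out.append(PhenotypeSet(env, dict(zip(pop.line_ids, y.tolist()))))
    return out
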