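"""Cross-environment stability of significant interaction pairs.

A pair that clears the Bonferroni threshold in several independent
year x location environments is far less likely to be an artefact of one
trial; the stability stage counts, per distinct pair, the environments in
which it was emitted by the scan and filters on that count.

Two notions of "stable" are shipped as presets: ``gt2`` keeps pairs seen in
more than two environments, ``half`` keeps pairs seen in at least half
(rounded up) of the environments that yielded any significant pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "StabilityRecord",
    "aggregate_stability",
    "resolve_min_envs",
    "select_stable",
    "stability_histogram",
]

PRESETS = ("gt2", "half")


@dataclass(frozen=True)
class StabilityRecord:
    marker_a: str
    marker_b: str
    env_count: int
    env_ids: tuple[str, ...]
    available_envs: int


def aggregate_stability(scan: pd.DataFrame, available_envs: int) -> list[StabilityRecord]:
    """Collapse a stacked scan table into one record per distinct pair.

    ``available_envs`` is the number of environments that produced at least
    one significant pair; it caps every env_count.  Output is sorted by
    descending environment count, then pair name.
    """
    if available_envs < 1:
        raise ValueError("available_envs must be >= 1")
    if scan.duplicated(subset=["env_id", "marker_a", "marker_b"]).any():
        raise ValueError("duplicate (environment, pair) rows in scan table")
    records: list[StabilityRecord] = []
    if len(scan):
        grouped = scan.groupby(["marker_a", "marker_b"], sort=True)["env_id"]
        for (ma, mb), envs in grouped:
            env_ids = tuple(sorted(envs))
            if len(env_ids) > available_envs:
                raise ValueError(
                    f"pair ({ma}, {mb}) seen in {len(env_ids)} environments "
                    f"but only {available_envs} available"
                )
            records.append(StabilityRecord(ma, mb, len(env_ids), env_ids, available_envs))
    records.sort(key=lambda r: (-r.env_count, r.marker_a, r.marker_b))
    return records


def resolve_min_envs(preset: str, available_envs: int) -> int:
    """Map a named stability preset to a minimum environment count."""
    if preset == "gt2":
        return 3
    if preset == "half":
        return math.ceil(available_envs / 2)
    raise ValueError(f"unknown stability preset {preset!r}; choose from {PRESETS}")


def select_stable(
    records: Sequence[StabilityRecord],
    min_envs: int | None = None,
    preset: str = "half",
) -> list[StabilityRecord]:
    """Keep records detected in at least ``min_envs`` environments.

    If ``min_envs`` is not given it is derived from ``preset`` and the
    records' ``available_envs``.  Monotone: raising ``min_envs`` never adds
    a pair.
    """
    if min_envs is None:
        available = records[0].available_envs if records else 1
        min_envs = resolve_min_envs(preset, available)
    if min_envs < 1:
        raise ValueError("min_envs must be >= 1")
    return [r for r in records if r.env_count >= min_envs]


def stability_histogram(records: Sequence[StabilityRecord]) -> dict[int, int]:
    """Number of pairs per environment count; values sum to len(records)."""
    hist: dict[int, int] = {}
    for r in records:
        hist[r.env_count] = hist.get(r.env_count, 0) + 1
    return dict(sorted(hist.items(), reverse=True))


def records_to_frame(records: Sequence[StabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker_a": r.marker_a,
                "marker_b": r.marker_b,
                "env_count": r.env_count,
                "env_ids": ",".join(r.env_ids),
                "available_envs": r.available_envs,
            }
            for r in records
        ],
        columns=["marker_a", "marker_b", "env_count", "env_ids", "available_envs"],
    )
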