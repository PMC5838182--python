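"""Coverage screening: expected caseload, percent coverage, roles, pairing.

A registry's completeness is screened against a national norm (113 new
cancer cases per year per 100,000 catchment population by default). A
province observing fewer cases than 100% of its expectation is a *sender*
— some of its residents are presumed registered elsewhere — and an
adjacent province above 100% is a *receiver*. Each sender is paired with
one adjacent receiver for downstream model fitting; the published 2008
pairings can be reproduced exactly through explicit overrides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .registry_io import (
    AdjacencyMap,
    CoverageConfig,
    ProvinceTable,
    load_table1_fixture,
)

_TOL = 1e-9

SENDER = "sender"
RECEIVER = "receiver"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class CoverageRecord:
    """Observed vs expected caseload and derived percent coverage.

    For records transcribed from the published coverage table only the
    percentage is known; observed/expected totals are then ``None``.
    """

    province_id: str
    coverage_percent: float
    observed_total: float | None = None
    expected_total: float | None = None

    def __post_init__(self) -> None:
        if self.coverage_percent < 0:
            raise ValueError("coverage_percent must be non-negative")
        if self.observed_total is not None and self.expected_total is not None:
            implied = 100.0 * self.observed_total / self.expected_total
            if abs(implied - self.coverage_percent) > _TOL * max(1.0, implied):
                raise ValueError(
                    f"{self.province_id}: coverage_percent {self.coverage_percent} "
                    f"inconsistent with observed/expected ({implied})"
                )

    @property
    def role(self) -> str:
        return classify(self.coverage_percent)


@dataclass(frozen=True)
class PairSpec:
    """One sender (coverage < 100%) paired with one adjacent receiver (> 100%)."""

    sender_id: str
    receiver_id: str

    @property
    def pair_id(self) -> str:
        return f"{self.sender_id}->{self.receiver_id}"


def expected_cases(population: float, config: CoverageConfig | None = None) -> float:
    """Expected annual caseload for a catchment population under the norm."""
    config = config or CoverageConfig()
    if population < 0:
        raise ValueError("population must be non-negative")
    return config.cases_per_100k * population / 100_000.0


def coverage_percent(observed: float, expected: float) -> float:
    """Observed cases as a percentage of the expected caseload."""
    if expected <= 0:
        raise ValueError("expected caseload must be positive")
    if observed < 0:
        raise ValueError("observed caseload must be non-negative")
    return 100.0 * observed / expected


def classify(coverage: float) -> str:
    """Role of a province given its percent coverage (strict 100% threshold)."""
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    if abs(coverage - 100.0) <= _TOL:
        return NEUTRAL
    return SENDER if coverage < 100.0 else RECEIVER


def screen(
    tables: Mapping[str, ProvinceTable], config: CoverageConfig | None = None
) -> list[CoverageRecord]:
    """CoverageRecord per province from observed totals and catchment populations."""
    records = []
    for pid in sorted(tables):
        table = tables[pid]
        exp = expected_cases(table.total_population, config)
        records.append(
            CoverageRecord(
                province_id=pid,
                coverage_percent=coverage_percent(table.total_count, exp),
                observed_total=table.total_count,
                expected_total=exp,
            )
        )
    return records


def table1_coverage_records() -> list[CoverageRecord]:
    """The packaged 2008 coverage table as CoverageRecords (percent only)."""
    frame = load_table1_fixture()
    return [
        CoverageRecord(province_id=str(pid), coverage_percent=float(pct))
        for pid, pct in frame["coverage_percent"].items()
    ]


def build_pairs(
    coverage: Sequence[CoverageRecord],
    adjacency: AdjacencyMap,
    overrides: Iterable[PairSpec] | Iterable[tuple[str, str]] | None = None,
) -> tuple[list[PairSpec], list[str]]:
    """Pair each sender with one adjacent receiver.

    Default rule: the adjacent receiver with the highest coverage, ties
    broken lexicographically by province id. ``overrides`` replaces the
    default choice for the senders it names (each override must still name
    an adjacent, genuinely over-covered receiver). Returns the pair list
    (sender-sorted) and the ids of senders with no adjacent receiver, which
    are also reported via a warning.
    """
    by_id = {r.province_id: r for r in coverage}
    adjacency.validate_against(by_id)
    override_map: dict[str, str] = {}
    for ov in overrides or []:
        sender, receiver = (ov.sender_id, ov.receiver_id) if isinstance(ov, PairSpec) else ov
        for pid in (sender, receiver):
            if pid not in by_id:
                raise ValueError(f"override references unknown province {pid!r}")
        if by_id[sender].role != SENDER:
            raise ValueError(f"override sender {sender!r} is not under-covered")
        if by_id[receiver].role != RECEIVER:
            raise ValueError(f"override receiver {receiver!r} is not over-covered")
        if not adjacency.adjacent(sender, receiver):
            raise ValueError(f"override pair {sender!r}->{receiver!r} not adjacent")
        override_map[sender] = receiver

    pairs: list[PairSpec] = []
    unpaired: list[str] = []
    for rec in sorted(coverage, key=lambda r: r.province_id):
        if rec.role != SENDER:
            continue
        if rec.province_id in override_map:
            pairs.append(PairSpec(rec.province_id, override_map[rec.province_id]))
            continue
        candidates = [
            by_id[n]
            for n in adjacency.neighbors(rec.province_id)
            if n in by_id and by_id[n].role == RECEIVER
        ]
        if not candidates:
            unpaired.append(rec.province_id)
            continue
        # highest coverage wins; ties go to the lexicographically first id
        best = sorted(candidates, key=lambda r: (-r.coverage_percent, r.province_id))[0]
        pairs.append(PairSpec(rec.province_id, best.province_id))
    if unpaired:
        warnings.warn(
            f"senders with no adjacent receiver left unpaired: {unpaired}",
            stacklevel=2,
        )
    return pairs, unpaired


class CoverageScreen(BaseEstimator):
    """Estimator-style wrapper around screening and pairing.

    Parameters
    ----------
    cases_per_100k : float
        Expected annual caseload norm per 100,000 catchment population.

    After ``fit(tables, adjacency=...)`` the instance exposes ``records_``,
    ``pairs_`` and ``unpaired_``.
    """

    def __init__(self, cases_per_100k: float = 113.0):
        self.cases_per_100k = cases_per_100k

    def fit(
        self,
        X: Mapping[str, ProvinceTable] | Sequence[CoverageRecord],
        y=None,
        *,
        adjacency: AdjacencyMap | None = None,
        overrides=None,
    ):
        if isinstance(X, Mapping):
            self.records_ = screen(X, CoverageConfig(self.cases_per_100k))
        else:
            self.records_ = list(X)
        self.roles_ = {r.province_id: r.role for r in self.records_}
        if adjacency is not None:
            self.pairs_, self.unpaired_ = build_pairs(
                self.records_, adjacency, overrides
            )
        else:
            self.pairs_, self.unpaired_ = [], []
        return self
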