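"""Identification statistics, marker-panel optimization, transferability.

Choosing the fewest markers whose union identifies every progeny individual
is a set-cover instance. The default solver is the classic greedy
max-coverage heuristic (largest gain first, fully specified tie-breaking,
hence deterministic, with the usual 1 - 1/e coverage guarantee at fixed
panel size); an exhaustive solver over subsets is provided as an oracle for
small marker counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .pcr import GenotypeCall
from .reporting import percent

__all__ = [
    "GenotypingMatrix",
    "MarkerPanel",
    "TransferabilityReport",
    "identification_stats",
    "combined_rate",
    "greedy_panel",
    "exact_minimal_panel",
    "transferability",
]

CALL_VALUES = tuple(c.value for c in GenotypeCall)


class GenotypingMatrix:
    """Marker x individual band-pattern calls for one population.

    Cells take the values of :class:`~indelmark.pcr.GenotypeCall`.
    ``marker_polymorphic`` records, per marker, whether the parental patterns
    were valid and distinguishable in this population (markers failing that
    are carried with ``False`` so transferability can count them).
    """

    def __init__(
        self,
        population_id: str,
        calls: pd.DataFrame,
        marker_polymorphic: Mapping[str, bool] | None = None,
    ) -> None:
        if calls.index.has_duplicates or calls.columns.has_duplicates:
            raise ValueError("marker and individual IDs must be unique")
        bad = set(calls.values.ravel()) - set(CALL_VALUES)
        if bad:
            raise ValueError(f"unknown call values: {sorted(bad)}")
        self.population_id = population_id
        self.calls = calls
        self.marker_polymorphic = dict(
            marker_polymorphic
            if marker_polymorphic is not None
            else {m: True for m in calls.index}
        )
        missing = set(calls.index) - set(self.marker_polymorphic)
        if missing:
            raise ValueError(f"polymorphism flag missing for markers: {sorted(missing)}")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def identified_by(self, marker_id: str) -> frozenset[str]:
        """Individuals showing both parental bands at this marker."""
        row = self.calls.loc[marker_id]
        return frozenset(row.index[row == GenotypeCall.BOTH_PARENTS.value])

    @classmethod
    def from_calls(
        cls,
        population_id: str,
        calls: Mapping[str, Mapping[str, GenotypeCall | str]],
        marker_polymorphic: Mapping[str, bool] | None = None,
    ) -> "GenotypingMatrix":
        """Build from a nested mapping marker_id -> individual_id -> call."""
        df = pd.DataFrame(
            {
                ind: {m: str(getattr(c, "value", c)) for m, c in row.items()}
                for ind, row in _transpose(calls).items()
            }
        )
        df = df.loc[list(calls)]  # preserve marker order
        return cls(population_id, df, marker_polymorphic)

    def to_tsv(self, path: str) -> None:
        self.calls.to_csv(path, sep="\t", index_label="marker_id")

    @classmethod
    def from_tsv(cls, path: str, population_id: str = "") -> "GenotypingMatrix":
        df = pd.read_csv(path, sep="\t", index_col="marker_id", dtype=str)
        return cls(population_id or str(path), df)


def _transpose(calls: Mapping[str, Mapping[str, object]]) -> dict[str, dict[str, object]]:
    out: dict[str, dict[str, object]] = {}
    for marker, row in calls.items():
        for ind, call in row.items():
            out.setdefault(ind, {})[marker] = call
    return out


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered marker subset with its combined identification rate.

    ``identified_individuals`` is the union over panel markers of the
    individuals each marker identifies; ``combined_rate`` divides by all
    individuals in the population.
    """

    marker_ids: tuple[str, ...]
    identified_individuals: frozenset[str]
    n_individuals: int
    reached: bool = True

    @property
    def combined_rate(self) -> float:
        if self.n_individuals == 0:
            return 0.0
        return len(self.identified_individuals) / self.n_individuals

    @property
    def combined_rate_pct(self) -> float:
        return percent(len(self.identified_individuals), self.n_individuals)

    def as_dict(self) -> dict:
        return {
            "marker_ids": list(self.marker_ids),
            "n_identified": len(self.identified_individuals),
            "n_individuals": self.n_individuals,
            "combined_rate": self.combined_rate,
            "combined_rate_pct": self.combined_rate_pct,
            "reached": self.reached,
        }


def identification_stats(matrix: GenotypingMatrix) -> pd.DataFrame:
    """Per-marker count and rate of individuals identified as true hybrids.

    The denominator is all individuals in the population; ``callable_rate``
    is the secondary statistic that excludes missing cells from the
    denominator.
    """
    n = matrix.n_individuals
    rows = []
    for m in matrix.markers:
        row = matrix.calls.loc[m]
        count = int((row == GenotypeCall.BOTH_PARENTS.value).sum())
        n_callable = int((row != GenotypeCall.MISSING.value).sum())
        rows.append(
            {
                "marker_id": m,
                "n_identified": count,
                "rate": count / n if n else 0.0,
                "rate_pct": percent(count, n) if n else 0.0,
                "n_callable": n_callable,
                "callable_rate": count / n_callable if n_callable else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("marker_id")


def combined_rate(matrix: GenotypingMatrix, panel_marker_ids: Sequence[str]) -> MarkerPanel:
    """Union identification rate of a fixed marker panel."""
    unknown = [m for m in panel_marker_ids if m not in matrix.calls.index]
    if unknown:
        raise KeyError(f"markers not in matrix: {unknown}")
    identified: frozenset[str] = frozenset()
    for m in panel_marker_ids:
        identified |= matrix.identified_by(m)
    return MarkerPanel(
        marker_ids=tuple(panel_marker_ids),
        identified_individuals=identified,
        n_individuals=matrix.n_individuals,
    )


def greedy_panel(
    matrix: GenotypingMatrix,
    target_rate: float = 1.0,
    max_size: int | None = None,
) -> MarkerPanel:
    """Greedy max-coverage panel selection.

    Repeatedly adds the marker covering the most not-yet-identified
    individuals until the target rate is reached, the size cap is hit, or no
    marker adds coverage. Ties break by higher single-marker count, then by
    lexicographically smaller marker ID, so the result is deterministic. If
    the target is unreachable the best panel found is returned with
    ``reached=False``.
    """
    n = matrix.n_individuals
    cover = {m: matrix.identified_by(m) for m in matrix.markers}
    chosen: list[str] = []
    identified: frozenset[str] = frozenset()
    target_count = target_rate * n

    def done() -> bool:
        return len(identified) >= target_count - 1e-9

    while not done() and (max_size is None or len(chosen) < max_size):
        remaining = [m for m in matrix.markers if m not in chosen]
        if not remaining:
            break
        best = max(
            remaining,
            key=lambda m: (len(cover[m] - identified), len(cover[m]), _neg_lex(m)),
        )
        gain = cover[best] - identified
        if not gain:
            break
        chosen.append(best)
        identified |= gain
    return MarkerPanel(
        marker_ids=tuple(chosen),
        identified_individuals=identified,
        n_individuals=n,
        reached=done(),
    )


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smaller ID."""

    def __lt__(self, other) -> bool:
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:
        return str.__lt__(self, other)

    def __le__(self, other) -> bool:  # pragma: no cover - completeness
        return str.__ge__(self, other)

    def __ge__(self, other) -> bool:  # pragma: no cover - completeness
        return str.__le__(self, other)


EXACT_SOLVER_MAX_MARKERS = 20


def exact_minimal_panel(matrix: GenotypingMatrix) -> MarkerPanel:
    """Exhaustive smallest panel achieving the maximum achievable coverage.

    Enumerates subsets by increasing size (bitmask unions), returning the
    first — hence lexicographically smallest — panel of minimum cardinality.
    Refuses more than 20 markers; use :func:`greedy_panel` beyond that.
    """
    from itertools import combinations

    markers = sorted(matrix.markers)
    if len(markers) > EXACT_SOLVER_MAX_MARKERS:
        raise ValueError(
            f"{len(markers)} markers exceed the exhaustive solver cap of "
            f"{EXACT_SOLVER_MAX_MARKERS}; use greedy_panel instead"
        )
    individuals = matrix.individuals
    bit = {ind: 1 << i for i, ind in enumerate(individuals)}
    masks = {
        m: sum(bit[i] for i in matrix.identified_by(m)) for m in markers
    }
    best_possible = 0
    for m in markers:
        best_possible |= masks[m]
    target = bin(best_possible).count("1")
    if target == 0:
        return MarkerPanel(
            marker_ids=(),
            identified_individuals=frozenset(),
            n_individuals=matrix.n_individuals,
            reached=True,
        )
    for k in range(1, len(markers) + 1):
        for combo in combinations(markers, k):
            mask = 0
            for m in combo:
                mask |= masks[m]
            if bin(mask).count("1") == target:
                identified = frozenset(
                    ind for ind in individuals if mask & bit[ind]
                )
                return MarkerPanel(
                    marker_ids=tuple(combo),
                    identified_individuals=identified,
                    n_individuals=matrix.n_individuals,
                )
    raise AssertionError("unreachable: full marker set achieves max coverage")


@dataclass(frozen=True)
class TransferabilityReport:
    """Hybrid identification and marker universality in a new population.

    An effective marker retains valid polymorphic parental patterns in the
    new population and identifies at least one individual; a true hybrid
    shows both parental bands at >= 1 effective marker.
    """

    population_id: str
    n_f1: int
    n_true_hybrid: int
    n_total_markers: int
    n_effective_markers: int
    n_polymorphic_markers: int

    @property
    def hybrid_rate(self) -> float | None:
        return self.n_true_hybrid / self.n_f1 if self.n_f1 else None

    @property
    def hybrid_rate_pct(self) -> float | None:
        return percent(self.n_true_hybrid, self.n_f1) if self.n_f1 else None

    @property
    def universality_rate(self) -> float | None:
        if not self.n_total_markers:
            return None
        return self.n_effective_markers / self.n_total_markers

    @property
    def universality_rate_pct(self) -> float | None:
        if not self.n_total_markers:
            return None
        return percent(self.n_effective_markers, self.n_total_markers)

    def as_dict(self) -> dict:
        return {
            "population_id": self.population_id,
            "n_f1": self.n_f1,
            "n_true_hybrid": self.n_true_hybrid,
            "hybrid_rate_pct": self.hybrid_rate_pct,
            "n_total_markers": self.n_total_markers,
            "n_polymorphic_markers": self.n_polymorphic_markers,
            "n_effective_markers": self.n_effective_markers,
            "universality_rate_pct": self.universality_rate_pct,
        }


def transferability(
    matrix: GenotypingMatrix, reference_marker_list: Sequence[str]
) -> TransferabilityReport:
    """Evaluate a reference marker panel on a new population's matrix.

    ``reference_marker_list`` is the validated panel from the discovery
    population. Markers absent from the matrix count as non-polymorphic.
    Parental polymorphism and per-marker informativeness are tracked
    separately: ``n_polymorphic_markers`` counts the first condition alone,
    ``n_effective_markers`` requires both.
    """
    present = set(matrix.calls.index)
    polymorphic = [
        m
        for m in reference_marker_list
        if m in present and matrix.marker_polymorphic.get(m, False)
    ]
    effective = [m for m in polymorphic if matrix.identified_by(m)]
    hybrids: set[str] = set()
    for m in effective:
        hybrids |= matrix.identified_by(m)
    return TransferabilityReport(
        population_id=matrix.population_id,
        n_f1=matrix.n_individuals,
        n_true_hybrid=len(hybrids),
        n_total_markers=len(reference_marker_list),
        n_effective_markers=len(effective),
        n_polymorphic_markers=len(polymorphic),
    )
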