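"""Cumulative adversity scoring, delay-task scoring, and hot-deck imputation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Percentile cutoffs for continuous adversity components.
LOW_TAIL_PERCENTILE = 15.0
HIGH_TAIL_PERCENTILE = 85.0
DEFAULT_N_IMPUTATIONS = 30

SNACK_DELAYS_S = (10, 20, 15, 30)
BEHAVIOR_CODE_RANGE = (1, 7)
LATENCY_CODE_RANGE = (1, 2)
GLOBAL_COOPERATION_INCLUDED = 3

COMPONENT_KINDS = ("binary", "continuous_low_tail", "continuous_high_tail")


@dataclass
class AdversityComponent:
    """One adversity marker: binary points or a continuous measure
    dichotomized at a tail percentile."""

    name: str
    kind: str
    values: np.ndarray
    cutoff_percentile: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in COMPONENT_KINDS:
            raise ValidationError(f"unknown component kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "binary":
            ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0))
            if not ok.all():
                raise ValidationError(
                    f"component {self.name!r}: binary values must be 0/1/missing"
                )
            if self.cutoff_percentile is not None:
                raise ValidationError("binary components take no cutoff percentile")
        else:
            default = (
                LOW_TAIL_PERCENTILE
                if self.kind == "continuous_low_tail"
                else HIGH_TAIL_PERCENTILE
            )
            if self.cutoff_percentile is None:
                self.cutoff_percentile = default
            elif self.cutoff_percentile != default:
                raise ValidationError(
                    f"component {self.name!r}: {self.kind} uses the "
                    f"{default:g}th percentile"
                )

    def with_values(self, values: np.ndarray) -> "AdversityComponent":
        return AdversityComponent(
            self.name,
            self.kind,
            values,
            None if self.kind == "binary" else self.cutoff_percentile,
        )


@dataclass
class AdversityScore:
    """Summed adversity points per sample (complete-case semantics)."""

    score: np.ndarray  # float array; NaN where any component missing
    n_components: int
    complete_case: np.ndarray  # bool per sample


@dataclass
class SnackDelayRecord:
    """Four-trial delay-task record: (behavior_code, latency_code, delay_s)
    per trial plus a 0-3 global cooperation rating."""

    trials: list[tuple[int, int, float]]
    global_cooperation: int

    def __post_init__(self) -> None:
        if len(self.trials) != 4:
            raise ValidationError("record must have exactly 4 trials")
        delays = tuple(t[2] for t in self.trials)
        if delays != SNACK_DELAYS_S:
            raise ValidationError(f"trial delays must be {SNACK_DELAYS_S}, got {delays}")
        if self.global_cooperation not in (0, 1, 2, 3):
            raise ValidationError("global_cooperation must be 0-3")


def dichotomize_component(comp: AdversityComponent) -> np.ndarray:
    """Per-sample adversity points (0/1, NaN propagated).

    Binary components pass through; continuous ones score a point strictly
    below the empirical 15th (low tail) or strictly above the 85th (high
    tail) percentile, computed by linear interpolation over non-missing
    values. Ties at the cutoff score 0.
    """
    v = comp.values
    observed = v[~np.isnan(v)]
    if observed.size == 0:
        raise ValidationError(f"component {comp.name!r} is entirely missing")
    if comp.kind == "binary":
        return v.copy()
    if observed.size < 10:
        raise ValidationError(
            f"component {comp.name!r}: need >= 10 observed values to dichotomize"
        )
    cutoff = float(np.percentile(observed, comp.cutoff_percentile))
    points = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    if comp.kind == "continuous_low_tail":
        points[ok] = (v[ok] < cutoff).astype(float)
    else:
        points[ok] = (v[ok] > cutoff).astype(float)
    return points


def adversity_score(components: list[AdversityComponent]) -> AdversityScore:
    """Sum of component points; samples with any missing component get a
    missing score and ``complete_case = False``."""
    if not components:
        raise ValidationError("empty component list")
    n = components[0].values.shape[0]
    for c in components:
        if c.values.shape[0] != n:
            raise ValidationError("components do not share a sample index")
    points = np.stack([dichotomize_component(c) for c in components])
    complete = ~np.isnan(points).any(axis=0)
    score = np.where(complete, np.nansum(points, axis=0), np.nan)
    return AdversityScore(score=score, n_components=len(components), complete_case=complete)


def hot_deck_impute(
    components: list[AdversityComponent],
    m: int = DEFAULT_N_IMPUTATIONS,
    seed: int = 0,
) -> list[list[AdversityComponent]]:
    """Hot-deck multiple imputation of missing component values.

    Each missing cell is replaced by a uniformly drawn observed value of the
    same component, independently per imputed dataset. Returns ``m``
    completed component lists; reproducible under ``seed``.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    for c in components:
        if np.isnan(c.values).all():
            raise ValidationError(f"component {c.name!r} has no donor values")
    rng = np.random.default_rng(seed)
    out: list[list[AdversityComponent]] = []
    for _ in range(m):
        completed = []
        for c in components:
            v = c.values.copy()
            miss = np.isnan(v)
            if miss.any():
                donors = c.values[~miss]
                v[miss] = rng.choice(donors, size=int(miss.sum()), replace=True)
            completed.append(c.with_values(v))
        out.append(completed)
    return out


def score_snack_trial(behavior_code: int, latency_code: int) -> int:
    """Trial total = behavior code (1-7) + latency code (1-2), range 2-9."""
    lo_b, hi_b = BEHAVIOR_CODE_RANGE
    lo_l, hi_l = LATENCY_CODE_RANGE
    if not (isinstance(behavior_code, (int, np.integer)) and lo_b <= behavior_code <= hi_b):
        raise ValidationError(f"behavior_code must be an integer in [{lo_b}, {hi_b}]")
    if not (isinstance(latency_code, (int, np.integer)) and lo_l <= latency_code <= hi_l):
        raise ValidationError(f"latency_code must be an integer in [{lo_l}, {hi_l}]")
    return int(behavior_code) + int(latency_code)


def snack_delay_outcome(rec: SnackDelayRecord, aggregate: str = "mean") -> float | None:
    """Aggregate the four trial totals; higher = better delay ability.

    Children without full task cooperation (global score != 3) are excluded
    (returns None). Default aggregation is the mean; 'sum' is available.
    """
    if rec.global_cooperation != GLOBAL_COOPERATION_INCLUDED:
        return None
    totals = [score_snack_trial(b, l) for b, l, _ in rec.trials]
    if aggregate == "mean":
        return float(np.mean(totals))
    if aggregate == "sum":
        return float(np.sum(totals))
    raise ValidationError(f"unknown aggregate {aggregate!r}")
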