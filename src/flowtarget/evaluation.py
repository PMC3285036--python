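"""Ranking evaluation: interpolated precision–recall / mAP and the top-k
average-position table used to compare the flow method with its baselines."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TopKRow:
    fraction: float
    k: int
    count: int
    average_position: float | None  # None when no true target in the window


@dataclass
class EvalReport:
    method: str
    pr_points: list[tuple[float, float]] = field(default_factory=list)
    map_score: float | None = None
    topk: list[TopKRow] = field(default_factory=list)


def precision_recall(
    ranking: list[str], truth: set[str], method: str = ""
) -> EvalReport:
    """Interpolated average precision over the attained recall levels.

    At each recall level attained when a true target is reached, the
    interpolated precision is the maximum precision at that or any deeper
    cutoff; the mean of these values over the attained levels is the mAP.
    A ranking with all true targets first scores 1.
    """
    if not truth:
        raise ValueError("empty truth set")
    missing = truth - set(ranking)
    if missing:
        raise ValueError(f"truth not in ranked universe: {sorted(missing)[:5]}")
    n_truth = len(truth)
    precisions: list[float] = []  # precision at each rank cutoff
    recalls: list[float] = []
    hits = 0
    for i, item in enumerate(ranking, start=1):
        if item in truth:
            hits += 1
        precisions.append(hits / i)
        recalls.append(hits / n_truth)
    pr_points: list[tuple[float, float]] = []
    hits = 0
    for i, item in enumerate(ranking):
        if item in truth:
            hits += 1
            level = hits / n_truth
            interp = max(precisions[i:])
            pr_points.append((level, interp))
    map_score = sum(p for _, p in pr_points) / len(pr_points)
    return EvalReport(method=method, pr_points=pr_points, map_score=map_score)


def topk_average_position(
    ranking: list[str],
    truth: set[str],
    fractions: list[float] = (0.01, 0.03, 0.15),
    method: str = "",
) -> EvalReport:
    """True-target count and mean 1-based rank inside each top fraction.

    k = round(fraction × universe size), at least 1. A window containing no
    true target reports an undefined average position (None, rendered N/A).
    """
    n = len(ranking)
    rows = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        k = max(1, round(frac * n))
        positions = [i for i, item in enumerate(ranking[:k], start=1) if item in truth]
        rows.append(
            TopKRow(
                fraction=frac,
                k=k,
                count=len(positions),
                average_position=(sum(positions) / len(positions)) if positions else None,
            )
        )
    return EvalReport(method=method, topk=rows)
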