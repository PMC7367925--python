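"""Fit-for-purpose test-method readiness scoring.

A readiness rubric has 13 categories (documentation level, performance
characteristics, robustness, suitability for HTS, ...) with 62 sub-items in
total, each carrying a maximum score.  Two experts score a method
independently; their sheets are averaged per sub-item when the overall
percentages differ by less than 20 percentage points, otherwise a third
scorer is required and all three sheets are averaged.  Per-category and
overall percentages of the maximum reachable points are classified into
traffic-light bands: high (>= 85%, green), intermediate (>= 50%, orange),
low (< 50%, red).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import BlockedStateError, InvalidValueError, SchemaError

N_CATEGORIES = 13
N_SUB_ITEMS = 62
HIGH_CUTOFF = 85.0
INTERMEDIATE_CUTOFF = 50.0
DISCREPANCY_CUTOFF = 20.0  # percentage points between two raters


@dataclass
class SubItem:
    item_id: str
    description: str
    max_score: float


@dataclass
class Category:
    category_id: int
    name: str
    sub_items: list[SubItem]


@dataclass
class ReadinessRubric:
    categories: list[Category]
    version: str = "1"

    def items(self) -> list[SubItem]:
        return [it for cat in self.categories for it in cat.sub_items]

    def max_points(self) -> float:
        return sum(it.max_score for it in self.items())

    def validate(self) -> None:
        ids = [it.item_id for it in self.items()]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item ids: {dupes}")
        cat_ids = [c.category_id for c in self.categories]
        if len(set(cat_ids)) != len(cat_ids):
            raise SchemaError("duplicate category ids")
        for it in self.items():
            if not it.max_score > 0:
                raise SchemaError(f"item {it.item_id}: max_score must be > 0")


def default_rubric() -> ReadinessRubric:
    """The standard 13-category / 62-sub-item rubric as a structural skeleton.

    Category names follow the published readiness scheme; sub-item texts are
    placeholders — load the full criteria from a config file for real
    evaluations.
    """
    names = [
        "Test definition and rationale", "Basic test description",
        "Test system characterization", "Exposure scheme and endpoints",
        "Standard operating procedure", "Documentation level",
        "Positive and negative controls", "Performance characteristics",
        "Robustness", "Prediction model", "Applicability domain",
        "Regulatory documentation", "High-throughput suitability",
    ]
    # 10 categories of 5 sub-items + 3 of 4 = 62
    sizes = [5] * 10 + [4] * 3
    categories = []
    counter = 1
    for cat_id, (name, size) in enumerate(zip(names, sizes), start=1):
        subs = [SubItem(item_id=f"{cat_id}.{j}",
                        description=f"sub-item {counter + j - 1} (placeholder)",
                        max_score=5.0)
                for j in range(1, size + 1)]
        counter += size
        categories.append(Category(cat_id, name, subs))
    rubric = ReadinessRubric(categories, version="default-skeleton")
    rubric.validate()
    return rubric


def load_rubric(config: str | Path | dict) -> ReadinessRubric:
    """Load and validate a rubric from a YAML file or a parsed dict."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text(encoding="utf-8"))
    try:
        categories = [
            Category(
                category_id=int(c["category_id"]), name=str(c["name"]),
                sub_items=[SubItem(str(s["item_id"]), str(s.get("description", "")),
                                   float(s["max_score"]))
                           for s in c["sub_items"]],
            )
            for c in config["categories"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed rubric config: {exc}") from exc
    rubric = ReadinessRubric(categories, version=str(config.get("version", "1")))
    rubric.validate()
    return rubric


@dataclass
class ScoreSheet:
    method_id: str
    rater_id: str
    scores: dict[str, float]  # item_id -> points
    timestamp: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreSheet":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(method_id=str(d["method_id"]), rater_id=str(d["rater_id"]),
                   scores={str(k): float(v) for k, v in d["scores"].items()},
                   timestamp=str(d.get("timestamp", "")))


def _check_sheet(rubric: ReadinessRubric, sheet: ScoreSheet) -> None:
    item_ids = {it.item_id: it for it in rubric.items()}
    missing = sorted(set(item_ids) - set(sheet.scores))
    if missing:
        raise SchemaError(f"sheet {sheet.rater_id!r} is missing items: {missing}")
    extra = sorted(set(sheet.scores) - set(item_ids))
    if extra:
        raise SchemaError(f"sheet {sheet.rater_id!r} has unknown items: {extra}")
    for item_id, score in sheet.scores.items():
        mx = item_ids[item_id].max_score
        if not (0.0 <= score <= mx):
            raise InvalidValueError(
                f"sheet {sheet.rater_id!r}: score {score} for {item_id} outside [0, {mx}]")


def overall_percent(rubric: ReadinessRubric, scores: dict[str, float]) -> float:
    return 100.0 * sum(scores.values()) / rubric.max_points()


@dataclass
class Aggregation:
    method_id: str
    mean_scores: dict[str, float]
    per_rater_percent: dict[str, float]
    discrepancy_percent: float  # percentage points
    third_rater_required: bool
    raters_used: list[str]
    per_item_discrepancy: dict[str, float] = field(default_factory=dict)


def aggregate_raters(rubric: ReadinessRubric, sheets: list[ScoreSheet]) -> Aggregation:
    """Average >= 2 complete score sheets for one method.

    With two raters, the discrepancy is the absolute difference of their
    overall percentages; >= 20 percentage points requires a third rater.  With
    three sheets the mean of all three is taken (discrepancy reported as the
    largest pairwise difference).
    """
    if len(sheets) < 2:
        raise InvalidValueError("need at least two score sheets")
    methods = {s.method_id for s in sheets}
    if len(methods) != 1:
        raise InvalidValueError(f"sheets refer to different methods: {sorted(methods)}")
    for s in sheets:
        _check_sheet(rubric, s)
    item_ids = [it.item_id for it in rubric.items()]
    mean_scores = {i: sum(s.scores[i] for s in sheets) / len(sheets) for i in item_ids}
    per_item_disc = {i: max(s.scores[i] for s in sheets) - min(s.scores[i] for s in sheets)
                     for i in item_ids}
    per_rater = {s.rater_id: overall_percent(rubric, s.scores) for s in sheets}
    percents = list(per_rater.values())
    discrepancy = max(percents) - min(percents)
    third_needed = len(sheets) == 2 and discrepancy >= DISCREPANCY_CUTOFF
    return Aggregation(
        method_id=sheets[0].method_id, mean_scores=mean_scores,
        per_rater_percent=per_rater, discrepancy_percent=float(discrepancy),
        third_rater_required=third_needed,
        raters_used=[s.rater_id for s in sheets],
        per_item_discrepancy=per_item_disc,
    )


def classify_readiness(percent: float,
                       high_cutoff: float = HIGH_CUTOFF,
                       intermediate_cutoff: float = INTERMEDIATE_CUTOFF) -> str:
    """Traffic-light band for an overall or per-category percentage.

    >= 85 high (green), >= 50 intermediate (orange), < 50 low (red).  The
    shared boundary values belong to the better band.
    """
    if not (0.0 <= percent <= 100.0):
        raise InvalidValueError(f"percent must be in [0, 100], got {percent!r}")
    if percent >= high_cutoff:
        return "high"
    if percent >= intermediate_cutoff:
        return "intermediate"
    return "low"


@dataclass
class ReadinessReport:
    method_id: str
    per_category_percent: dict[int, float]
    per_category_band: dict[int, str]
    overall_percent: float
    band: str
    raters_used: list[str]
    third_rater_required: bool

    def to_json_obj(self) -> dict:
        return {
            "method_id": self.method_id,
            "per_category_percent": self.per_category_percent,
            "per_category_band": self.per_category_band,
            "overall_percent": self.overall_percent,
            "band": self.band,
            "raters_used": self.raters_used,
        }

    def to_table(self) -> str:
        marker = {"high": "green", "intermediate": "orange", "low": "red"}
        lines = [f"Readiness report for {self.method_id}",
                 f"{'category':>10}  {'%':>6}  band"]
        for cid in sorted(self.per_category_percent):
            pct = self.per_category_percent[cid]
            band = self.per_category_band[cid]
            lines.append(f"{cid:>10}  {pct:6.1f}  {marker[band]}")
        lines.append(f"{'overall':>10}  {self.overall_percent:6.1f}  {marker[self.band]}")
        return "\n".join(lines)


def score_method(rubric: ReadinessRubric, aggregated: Aggregation) -> ReadinessReport:
    """Sum the per-item mean scores into category and overall percentages.

    The overall percentage is points-weighted (total points over total
    maximum), not an average of category percentages.  Refuses aggregations
    still awaiting a third rater.
    """
    if aggregated.third_rater_required:
        raise BlockedStateError(
            f"method {aggregated.method_id!r}: rater discrepancy "
            f"{aggregated.discrepancy_percent:.1f} points requires a third scorer")
    per_cat_pct: dict[int, float] = {}
    per_cat_band: dict[int, str] = {}
    for cat in rubric.categories:
        got = sum(aggregated.mean_scores[it.item_id] for it in cat.sub_items)
        mx = sum(it.max_score for it in cat.sub_items)
        pct = 100.0 * got / mx
        per_cat_pct[cat.category_id] = pct
        per_cat_band[cat.category_id] = classify_readiness(pct)
    overall = overall_percent(rubric, aggregated.mean_scores)
    return ReadinessReport(
        method_id=aggregated.method_id,
        per_category_percent=per_cat_pct, per_category_band=per_cat_band,
        overall_percent=overall, band=classify_readiness(overall),
        raters_used=aggregated.raters_used,
        third_rater_required=False,
    )
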