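"""Clinical interval routing for algorithm TPS scores.

PD-L1 TPS is reported in three clinical categories (<1%, 1-49%, >=50%), but
scores near the 1% and 50% decision cut-offs are where inter-observer
variation concentrates. The router therefore assigns every algorithm score
to one of five workflow bands:

    [0, 1)    confident_negative   auto-report pending confirmation
    [1, 5)    unconfident_low      manual review required
    [5, 40)   confident_mid        auto-report pending confirmation
    [40, 60)  unconfident_high     manual review required
    [60, 100] confident_positive   auto-report pending confirmation

Unconfident cases are blocked until a pathologist enters a score; the final
clinical category always follows the final (possibly pathologist-entered)
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .evaluate import clinical_category

__all__ = [
    "IntervalScheme",
    "IntervalDecision",
    "CaseRecord",
    "PendingReviewError",
    "default_scheme",
    "assign_interval",
    "route_case",
    "ACTION_AUTO", "ACTION_REVIEW",
]

ACTION_AUTO = "auto_report_pending_confirmation"
ACTION_REVIEW = "manual_review_required"

DEFAULT_EDGES = (1.0, 5.0, 40.0, 60.0)
DEFAULT_LABELS = ("confident_negative", "unconfident_low", "confident_mid",
                  "unconfident_high", "confident_positive")
DEFAULT_ACTIONS = (ACTION_AUTO, ACTION_REVIEW, ACTION_AUTO, ACTION_REVIEW,
                   ACTION_AUTO)


class PendingReviewError(RuntimeError):
    """An unconfident case cannot be finalised without a pathologist score."""


@dataclass(frozen=True)
class IntervalScheme:
    """Half-open bands [lo, hi) partitioning [0, 100]; the last band is closed."""

    edges: tuple[float, ...] = DEFAULT_EDGES
    labels: tuple[str, ...] = DEFAULT_LABELS
    actions: tuple[str, ...] = DEFAULT_ACTIONS

    def __post_init__(self):
        e = tuple(float(x) for x in self.edges)
        if any(b <= a for a, b in zip(e, e[1:])) or (e and (e[0] <= 0 or
                                                            e[-1] >= 100)):
            raise ValueError("edges must be strictly increasing within (0,100)")
        if len(self.labels) != len(e) + 1 or len(self.actions) != len(e) + 1:
            raise ValueError("need one label and action per band")
        if any(a not in (ACTION_AUTO, ACTION_REVIEW) for a in self.actions):
            raise ValueError("unknown band action")
        object.__setattr__(self, "edges", e)

    def band_index(self, tps: float) -> int:
        if not 0.0 <= tps <= 100.0:
            raise ValueError("TPS must lie in [0, 100]")
        for i, edge in enumerate(self.edges):
            if tps < edge:
                return i
        return len(self.edges)

    def band_of(self, tps: float) -> str:
        return self.labels[self.band_index(tps)]

    def to_dict(self) -> dict:
        return {"edges": list(self.edges), "labels": list(self.labels),
                "actions": list(self.actions)}

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalScheme":
        return cls(edges=tuple(d["edges"]), labels=tuple(d["labels"]),
                   actions=tuple(d["actions"]))


@dataclass
class IntervalDecision:
    """The routing outcome for one algorithm TPS."""

    tps_percent: float
    band: str
    clinical_category: str
    action: str
    final_score: Optional[float] = None

    @property
    def needs_review(self) -> bool:
        return self.action == ACTION_REVIEW


@dataclass
class CaseRecord:
    """A finalised (or pending) case with score provenance."""

    decision: IntervalDecision
    status: str                       # "finalized" or "pending_review"
    final_score: Optional[float]
    final_category: Optional[str]
    provenance: str                   # algorithm / pathologist_confirmed /
                                      # pathologist_overridden / pending


def default_scheme() -> IntervalScheme:
    """The review scheme with edges at 1, 5, 40 and 60 TPS points."""
    return IntervalScheme()


def assign_interval(tps: float,
                    scheme: IntervalScheme | None = None) -> IntervalDecision:
    """Map an algorithm TPS to its workflow band and clinical category."""
    scheme = scheme or default_scheme()
    i = scheme.band_index(tps)
    return IntervalDecision(tps_percent=float(tps), band=scheme.labels[i],
                            clinical_category=clinical_category(tps),
                            action=scheme.actions[i])


def route_case(decision: IntervalDecision,
               pathologist_score: Optional[float] = None,
               *, strict: bool = False) -> CaseRecord:
    """Finalise a case, enforcing mandatory review of unconfident bands.

    An unconfident case without a pathologist score stays pending (or, with
    ``strict``, raises :class:`PendingReviewError`). A supplied pathologist
    score always takes precedence and sets the provenance to confirmed or
    overridden depending on whether it changes the score.
    """
    if pathologist_score is not None and not 0 <= pathologist_score <= 100:
        raise ValueError("pathologist score must lie in [0, 100]")
    if decision.needs_review and pathologist_score is None:
        if strict:
            raise PendingReviewError(
                "unconfident band requires a pathologist-entered score")
        return CaseRecord(decision=decision, status="pending_review",
                          final_score=None, final_category=None,
                          provenance="pending")
    if pathologist_score is None:
        final = decision.tps_percent
        provenance = "algorithm"
    else:
        final = float(pathologist_score)
        provenance = ("pathologist_confirmed"
                      if final == decision.tps_percent
                      else "pathologist_overridden")
    decision.final_score = final
    return CaseRecord(decision=decision, status="finalized",
                      final_score=final,
                      final_category=clinical_category(final),
                      provenance=provenance)
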