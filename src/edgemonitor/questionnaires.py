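"""Daily symptom-diary scoring and the monthly gated mood questionnaires.

The daily diary is nine ordinal items; the overall symptom score is their
sum and feeds the personalised alerting thresholds.  Emotional well-being
is tracked monthly with a gated flow: the two-item screeners PHQ-2
(depression) and GAD-2 (anxiety) are always asked, and a screener score at
or above its gate (standard screening cutoff 3) triggers the corresponding
full instrument, PHQ-8 (0–24) or GAD-7 (0–21).  Severe full-scale scores,
or a large jump since the previous administration, flag the patient to
their GP.  Questionnaire and diary scores also drive the selection of
self-management video content.

The exact diary item wording/scale and the trial's flow diagrams are
configuration, not code: item range, gates, severity cutoffs and the jump
size are all fields of :class:`DiaryConfig` / :class:`MoodConfig` with
documented standard defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable, Sequence

__all__ = [
    "DiaryConfig",
    "MoodConfig",
    "MoodResult",
    "ContentRule",
    "score_symptom_diary",
    "administer_mood_flow",
    "gp_flag",
    "select_content",
    "is_mood_due",
]

PHQ2_ITEMS, PHQ8_ITEMS = 2, 8
GAD2_ITEMS, GAD7_ITEMS = 2, 7
ITEM_MAX_MOOD = 3  # PHQ/GAD items are scored 0-3


@dataclass(frozen=True)
class DiaryConfig:
    n_items: int = 9
    item_min: int = 0
    item_max: int = 3

    def __post_init__(self) -> None:
        if self.item_min >= self.item_max:
            raise ValueError("item_min must be < item_max")
        if self.n_items < 1:
            raise ValueError("n_items must be positive")


@dataclass(frozen=True)
class MoodConfig:
    phq2_gate: int = 3
    gad2_gate: int = 3
    phq8_severe: int = 20
    gad7_severe: int = 15
    increase_delta: int = 10
    interval_days: int = 28


@dataclass(frozen=True)
class MoodResult:
    phq2: int
    gad2: int
    phq8: int | None = None
    gad7: int | None = None
    phq_full_administered: bool = False
    gad_full_administered: bool = False
    gp_flagged: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.phq2 <= PHQ2_ITEMS * ITEM_MAX_MOOD:
            raise ValueError("phq2 out of range")
        if not 0 <= self.gad2 <= GAD2_ITEMS * ITEM_MAX_MOOD:
            raise ValueError("gad2 out of range")
        if (self.phq8 is not None) != self.phq_full_administered:
            raise ValueError("phq8 present iff the PHQ gate passed")
        if (self.gad7 is not None) != self.gad_full_administered:
            raise ValueError("gad7 present iff the GAD gate passed")
        if self.phq8 is not None and not 0 <= self.phq8 <= PHQ8_ITEMS * ITEM_MAX_MOOD:
            raise ValueError("phq8 out of range")
        if self.gad7 is not None and not 0 <= self.gad7 <= GAD7_ITEMS * ITEM_MAX_MOOD:
            raise ValueError("gad7 out of range")


def _score_items(answers: Sequence[int], n: int, lo: int, hi: int, name: str) -> int:
    if len(answers) != n:
        raise ValueError(f"{name} needs exactly {n} answers, got {len(answers)}")
    for i, a in enumerate(answers):
        if not isinstance(a, int) or isinstance(a, bool):
            raise ValueError(f"{name} item {i + 1} is not an integer: {a!r}")
        if not lo <= a <= hi:
            raise ValueError(f"{name} item {i + 1} value {a} outside [{lo}, {hi}]")
    return sum(answers)


def score_symptom_diary(answers: Sequence[int], config: DiaryConfig | None = None) -> int:
    """Overall symptom score: the sum of the nine ordinal diary items."""
    config = config or DiaryConfig()
    return _score_items(
        answers, config.n_items, config.item_min, config.item_max, "symptom diary"
    )


def administer_mood_flow(
    phq2_answers: Sequence[int],
    gad2_answers: Sequence[int],
    full_answer_source: Callable[[str], Sequence[int]],
    config: MoodConfig | None = None,
    previous: "MoodResult | None" = None,
) -> MoodResult:
    """Run the gated monthly mood flow and return a scored result.

    The screeners are scored first; a screener at or above its gate causes
    ``full_answer_source("phq8")`` / ``full_answer_source("gad7")`` to be
    called for the full instrument's answers.  A failed gate never triggers
    the full form.  The GP flag is evaluated against ``previous``.
    """
    config = config or MoodConfig()
    phq2 = _score_items(phq2_answers, PHQ2_ITEMS, 0, ITEM_MAX_MOOD, "PHQ-2")
    gad2 = _score_items(gad2_answers, GAD2_ITEMS, 0, ITEM_MAX_MOOD, "GAD-2")

    phq8 = gad7 = None
    if phq2 >= config.phq2_gate:
        phq8 = _score_items(full_answer_source("phq8"), PHQ8_ITEMS, 0, ITEM_MAX_MOOD, "PHQ-8")
    if gad2 >= config.gad2_gate:
        gad7 = _score_items(full_answer_source("gad7"), GAD7_ITEMS, 0, ITEM_MAX_MOOD, "GAD-7")

    result = MoodResult(
        phq2=phq2,
        gad2=gad2,
        phq8=phq8,
        gad7=gad7,
        phq_full_administered=phq8 is not None,
        gad_full_administered=gad7 is not None,
    )
    flagged = gp_flag(previous, result, config)
    return MoodResult(
        phq2=phq2,
        gad2=gad2,
        phq8=phq8,
        gad7=gad7,
        phq_full_administered=phq8 is not None,
        gad_full_administered=gad7 is not None,
        gp_flagged=flagged,
    )


def gp_flag(
    previous: MoodResult | None, current: MoodResult, config: MoodConfig | None = None
) -> bool:
    """Whether the current result indicates a major increase in anxiety or
    depression warranting a GP flag.

    Fires when a full-scale score reaches the severe cutoff (PHQ-8 ≥ 20 or
    GAD-7 ≥ 15 by default), or when a full-scale score increased by at
    least ``increase_delta`` over the previous administration's full score.
    """
    config = config or MoodConfig()
    if current.phq8 is not None and current.phq8 >= config.phq8_severe:
        return True
    if current.gad7 is not None and current.gad7 >= config.gad7_severe:
        return True
    if previous is not None:
        if (
            current.phq8 is not None
            and previous.phq8 is not None
            and current.phq8 - previous.phq8 >= config.increase_delta
        ):
            return True
        if (
            current.gad7 is not None
            and previous.gad7 is not None
            and current.gad7 - previous.gad7 >= config.increase_delta
        ):
            return True
    return False


@dataclass(frozen=True)
class ContentRule:
    """Maps one instrument's score band [lo, hi] to a content tag."""

    instrument: str  # one of: diary, phq2, phq8, gad2, gad7
    lo: int
    hi: int
    tag: str

    def __post_init__(self) -> None:
        if self.instrument not in {"diary", "phq2", "phq8", "gad2", "gad7"}:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if self.lo > self.hi:
            raise ValueError("band lo must be <= hi")


def select_content(
    diary_score: int,
    mood: MoodResult | None,
    profile_tags: Sequence[str],
    rules: Sequence[ContentRule],
) -> list[str]:
    """Deterministic selection of self-management content tags.

    Always-on profile tags (e.g. a smoking-cessation programme) come
    first, followed by the tag of each rule whose band contains the
    corresponding score, in rule order; duplicates keep their first
    position.  An instrument with rules but no matching band for the
    observed score raises ``ValueError`` (incomplete configuration); an
    instrument whose score is unavailable (gate not passed) is skipped.
    """
    scores: dict[str, int | None] = {"diary": diary_score}
    if mood is not None:
        scores.update(phq2=mood.phq2, gad2=mood.gad2, phq8=mood.phq8, gad7=mood.gad7)
    else:
        scores.update(phq2=None, gad2=None, phq8=None, gad7=None)

    out: list[str] = []
    for t in profile_tags:
        if t not in out:
            out.append(t)
    for instrument in ("diary", "phq2", "phq8", "gad2", "gad7"):
        score = scores[instrument]
        inst_rules = [r for r in rules if r.instrument == instrument]
        if score is None or not inst_rules:
            continue
        matched = [r for r in inst_rules if r.lo <= score <= r.hi]
        if not matched:
            raise ValueError(
                f"no content band covers {instrument} score {score}: config incomplete"
            )
        for r in matched:
            if r.tag not in out:
                out.append(r.tag)
    return out


def is_mood_due(
    last_completed: datetime | None, today: datetime, interval_days: int = 28
) -> bool:
    """Monthly cadence: due when never completed or ≥ interval_days elapsed.

    28 days rather than calendar months, for determinism across month
    lengths; exactly 28 days since completion counts as due.
    """
    if last_completed is None:
        return True
    return today - last_completed >= timedelta(days=interval_days)
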