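"""Adaptive peer-feedback algorithm and behavioral statistics.

The task: a participant first rates each stimulus on an integer 0–9
scale.  On peer-feedback trials a fabricated "group rating" is shown,
set 1, 2 or 3 points above or below the initial rating; when the target
would leave the scale the direction of the offset is reversed
(boundary reflection), so the displayed rating always stays in 0–9.
The participant then rates again (final rating).

Statistics:

* influence score — proportion of trials in a condition where the final
  rating differs from the initial one;
* conforming rate — among changed feedback trials, the fraction whose
  change moves toward the displayed group rating;
* paired contrast — paired t with two effect sizes: the field-standard
  d_z = mean(diff)/sd(diff), and the convention d = 2t/√df that this
  line of studies prints (both are reported so neither propagates
  silently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedValueError, ValidationError

CONDITIONS = ("peer_feedback", "non_feedback")
VALID_OFFSETS = (-3, -2, -1, 1, 2, 3)
RATING_MIN, RATING_MAX = 0, 9


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial (feedback trials carry offset and shown rating)."""

    subject: str
    stimulus: str
    condition: str
    initial: int
    offset: int | None
    shown: int | None
    final: int
    rt_ms: float

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        for name in ("initial", "final"):
            v = getattr(self, name)
            if not (RATING_MIN <= v <= RATING_MAX):
                raise ValidationError(f"{name} rating {v} outside [0, 9]")
        if self.condition == "peer_feedback":
            if self.offset not in VALID_OFFSETS:
                raise ValidationError(f"offset {self.offset} not in ±{{1,2,3}}")
            if self.shown is None or not (RATING_MIN <= self.shown <= RATING_MAX):
                raise ValidationError(f"shown rating {self.shown} outside [0, 9]")
        else:
            if self.offset is not None or self.shown is not None:
                raise ValidationError("non-feedback trial carries offset/shown")
        if self.rt_ms < 0:
            raise ValidationError(f"negative RT {self.rt_ms}")


def make_group_rating(initial: int, offset: int) -> int:
    """Displayed group rating for a given initial rating and intended offset.

    Returns ``initial + offset`` when that stays on the 0–9 scale;
    otherwise the offset direction is reversed and ``initial - offset``
    is returned.  The result is always a valid rating.

    >>> make_group_rating(2, +3)
    5
    >>> make_group_rating(2, -3)   # 2 - 3 < 0, direction reversed
    5
    """
    if offset not in VALID_OFFSETS:
        raise ParameterError(f"offset {offset} not in ±{{1,2,3}}")
    if not (RATING_MIN <= initial <= RATING_MAX):
        raise ParameterError(f"initial rating {initial} outside [0, 9]")
    target = initial + offset
    if RATING_MIN <= target <= RATING_MAX:
        return target
    return initial - offset


def influence_score(trials: Iterable[TrialRecord], condition: str) -> float:
    """Proportion of trials (within *condition*) whose final ≠ initial rating."""
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}")
    sel = [t for t in trials if t.condition == condition]
    if not sel:
        raise UndefinedValueError(f"no trials in condition {condition!r}")
    changed = sum(t.final != t.initial for t in sel)
    return changed / len(sel)


def conforming_rate(trials: Iterable[TrialRecord],
                    denominator: str = "changed") -> float:
    """Fraction of feedback trials whose rating change moves toward the
    displayed group rating.

    ``denominator="changed"`` (default) divides by changed feedback
    trials; ``denominator="all"`` divides by all feedback trials.
    """
    if denominator not in ("changed", "all"):
        raise ParameterError(f"unknown denominator {denominator!r}")
    fb = [t for t in trials if t.condition == "peer_feedback"]
    if not fb:
        raise UndefinedValueError("no peer-feedback trials")
    changed = [t for t in fb if t.final != t.initial]
    toward = sum(
        np.sign(t.final - t.initial) == np.sign(t.shown - t.initial)
        for t in changed
    )
    denom = len(changed) if denominator == "changed" else len(fb)
    if denom == 0:
        raise UndefinedValueError("no changed feedback trials")
    return toward / denom


class PairedContrast(NamedTuple):
    t: float
    df: int
    p: float
    d: float      # 2t/sqrt(df): the convention used by this study line
    d_z: float    # mean(diff)/sd(diff): conventional paired effect size


def paired_contrast(x: Sequence[float], y: Sequence[float]) -> PairedContrast:
    """Paired t-test with both effect-size conventions.

    ``d = 2t/√df`` reproduces the printed effect sizes of the study line
    this pipeline follows (e.g. t=3.66, df=26 → 1.44); ``d_z`` is the
    conventional paired standardized mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ParameterError(f"need n >= 3 pairs, got {n}")
    diff = x - y
    sd = diff.std(ddof=1)
    df = n - 1
    if sd == 0:
        m = diff.mean()
        t = 0.0 if m == 0 else math.copysign(math.inf, m)
        p = 1.0 if m == 0 else 0.0
        dz = t
    else:
        t, p = stats.ttest_rel(x, y)
        t, p = float(t), float(p)
        dz = diff.mean() / sd
    return PairedContrast(t=t, df=df, p=p, d=effect_size_from_t(t, df), d_z=dz)


def effect_size_from_t(t: float, df: int) -> float:
    """The study line's effect-size convention d = 2t/√df."""
    if df <= 0:
        raise ParameterError("df must be positive")
    return 2.0 * t / math.sqrt(df)


def response_rate(responders: int, total: int, decimals: int = 2) -> float:
    """Survey response rate as a percentage truncated to *decimals* places
    (e.g. 43/44 → 97.72)."""
    if not 0 <= responders <= total or total == 0:
        raise ParameterError("need 0 <= responders <= total, total > 0")
    scale = 10 ** decimals
    return math.floor(responders / total * 100 * scale) / scale


def summarize_subjects(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Per-subject behavioral summary (RT means, influence scores,
    conforming rate)."""
    by_subject: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_subject.setdefault(t.subject, []).append(t)
    rows = []
    for subj, ts in sorted(by_subject.items()):
        row: dict = {"subject": subj}
        for cond in CONDITIONS:
            sel = [t for t in ts if t.condition == cond]
            key = "fb" if cond == "peer_feedback" else "nf"
            row[f"rt_{key}"] = float(np.mean([t.rt_ms for t in sel])) if sel else np.nan
            try:
                row[f"influence_{key}"] = influence_score(ts, cond)
            except UndefinedValueError:
                row[f"influence_{key}"] = np.nan
        try:
            row["conforming_rate"] = conforming_rate(ts)
        except UndefinedValueError:
            row["conforming_rate"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def group_contrasts(summary: pd.DataFrame) -> pd.DataFrame:
    """Paired feedback vs non-feedback contrasts of RT and influence score."""
    out = []
    for label, (a, b) in {
        "rt_ms": ("rt_fb", "rt_nf"),
        "influence_score": ("influence_fb", "influence_nf"),
    }.items():
        sub = summary[[a, b]].dropna()
        c = paired_contrast(sub[a].to_numpy(), sub[b].to_numpy())
        out.append({"measure": label, "mean_feedback": sub[a].mean(),
                    "mean_non_feedback": sub[b].mean(), "t": c.t, "df": c.df,
                    "p": c.p, "d": c.d, "d_z": c.d_z})
    return pd.DataFrame(out).set_index("measure")
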