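"""Before/after physiological-response statistics for gait training sessions.

Each training session records a subject's peripheral capillary oxygen
saturation (SpO2, %) and heart rate (HR, beats/min) immediately before
and after a 15-minute exoskeleton-guided walk, once under the
population-average ("general") gait trajectory and once under the
individualized one.  The energy-cost proxy is the signed variation
(after - before) of each measure; the two guidance conditions are
compared subject-by-subject with a paired test.

The paired t-test is the default; an exact Wilcoxon signed-rank test
(average ranks for ties, zero differences dropped, exact sign-flip null
up to n = 25) is available as a distribution-free alternative.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .codec import ValidationError

SESSIONS = ("general", "individualized")
MEASURES = ("spo2", "hr")

SESSION_LABELS = {
    "general": "General-gait-treatment",
    "individualized": "Individualized-gait treatment",
}
MEASURE_LABELS = {"spo2": "SpO2 (%)", "hr": "HR (bpm)"}

_SPO2_RANGE = (70.0, 100.0)
_HR_RANGE = (30.0, 220.0)

_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class SessionRecord:
    """One subject's before/after vitals for one training session."""

    subject_id: str
    session: str
    spo2_before: float
    spo2_after: float
    hr_before: float
    hr_after: float

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValidationError(
                f"session must be one of {SESSIONS}, got {self.session!r}"
            )
        for name in ("spo2_before", "spo2_after"):
            v = getattr(self, name)
            if not (_SPO2_RANGE[0] <= v <= _SPO2_RANGE[1]):
                raise ValidationError(f"{name}={v} outside plausible range {_SPO2_RANGE}")
        for name in ("hr_before", "hr_after"):
            v = getattr(self, name)
            if not (_HR_RANGE[0] < v < _HR_RANGE[1]):
                raise ValidationError(f"{name}={v} outside plausible range {_HR_RANGE}")


def variation(record: SessionRecord) -> tuple[float, float]:
    """Signed (after - before) change of (SpO2, HR) for one session."""
    return (
        record.spo2_after - record.spo2_before,
        record.hr_after - record.hr_before,
    )


@dataclass(frozen=True)
class MeasureStats:
    """Per-subject variations of one measure in one session, with summary."""

    subject_ids: tuple[str, ...]
    variations: tuple[float, ...]
    mean: float
    sd: float  # sample SD (n-1)


@dataclass(frozen=True)
class VariationSummary:
    """Session x measure variation statistics for a cohort."""

    stats: dict[tuple[str, str], MeasureStats]  # (session, measure) -> stats


def summarize(records: Sequence[SessionRecord]) -> VariationSummary:
    """Mean and sample SD of per-subject variations, per session and measure."""
    by_session: dict[str, list[SessionRecord]] = {}
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.subject_id, r.session)
        if key in seen:
            raise ValidationError(f"duplicate record for subject/session {key}")
        seen.add(key)
        by_session.setdefault(r.session, []).append(r)

    out: dict[tuple[str, str], MeasureStats] = {}
    for session, recs in by_session.items():
        if len(recs) < 2:
            raise ValueError(f"session {session!r} has fewer than 2 records")
        recs = sorted(recs, key=lambda r: r.subject_id)
        ids = tuple(r.subject_id for r in recs)
        spo2 = np.array([variation(r)[0] for r in recs])
        hr = np.array([variation(r)[1] for r in recs])
        for measure, v in (("spo2", spo2), ("hr", hr)):
            out[(session, measure)] = MeasureStats(
                subject_ids=ids,
                variations=tuple(float(x) for x in v),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)),
            )
    return VariationSummary(stats=out)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a paired between-session test on one measure."""

    measure: str
    method: str
    subject_ids: tuple[str, ...]
    differences: tuple[float, ...]  # general change - individualized change
    statistic: float
    pvalue: float
    n: int


def _paired_changes(
    general: Sequence[SessionRecord],
    individualized: Sequence[SessionRecord],
    measure: str,
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    gmap = {r.subject_id: r for r in general}
    imap = {r.subject_id: r for r in individualized}
    if set(gmap) != set(imap):
        raise ValidationError(
            f"subject sets differ between sessions: "
            f"{sorted(set(gmap) ^ set(imap))}"
        )
    ids = tuple(sorted(gmap))
    k = MEASURES.index(measure)
    g = np.array([variation(gmap[s])[k] for s in ids])
    i = np.array([variation(imap[s])[k] for s in ids])
    return ids, g, i


def exact_wilcoxon_signed_rank(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for small paired samples.

    Zero differences are dropped; tied absolute differences receive average
    ranks.  The null distribution of W+ is built by exact sign-flip
    enumeration (dynamic programming over doubled ranks, exact for any tie
    pattern) for n <= 25; larger samples fall back to the tie-corrected
    normal approximation.  Returns (W+, p).
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; signed-rank test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n > _EXACT_WILCOXON_MAX_N:
        mu = n * (n + 1) / 4.0
        # tie-corrected variance of W+
        var = (ranks**2).sum() / 4.0
        z = (w_plus - mu) / np.sqrt(var)
        return w_plus, float(2.0 * sps.norm.sf(abs(z)))

    # doubled ranks are integers even with .5 average ranks
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2.0**n
    w2 = int(np.rint(2.0 * w_plus))
    p_low = float(counts[: w2 + 1].sum())
    p_high = float(counts[w2:].sum())
    p = min(1.0, 2.0 * min(p_low, p_high))
    return w_plus, p


def compare_sessions(
    general: Sequence[SessionRecord],
    individualized: Sequence[SessionRecord],
    measure: str = "hr",
    method: str = "paired_t",
) -> ComparisonResult:
    """Paired between-session test on per-subject variations of one measure.

    Differences are general-session change minus individualized-session
    change, paired by subject.  ``method`` is ``'paired_t'`` (exact t
    distribution, n-1 df) or ``'wilcoxon'`` (exact signed-rank).
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    ids, g, i = _paired_changes(general, individualized, measure)
    d = g - i
    if method == "paired_t":
        if np.all(d == 0.0):
            stat, p = 0.0, 1.0  # identical sessions: no evidence either way
        else:
            res = sps.ttest_rel(g, i)
            stat, p = float(res.statistic), float(res.pvalue)
    elif method == "wilcoxon":
        stat, p = exact_wilcoxon_signed_rank(d)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(
        measure=measure,
        method=method,
        subject_ids=ids,
        differences=tuple(float(x) for x in d),
        statistic=stat,
        pvalue=p,
        n=len(ids),
    )


def summary_to_frame(summary: VariationSummary) -> pd.DataFrame:
    """Tidy DataFrame of the summary (one row per session x measure)."""
    rows = []
    for (session, measure), st in sorted(summary.stats.items()):
        rows.append(
            {
                "session": session,
                "measure": measure,
                "n": len(st.variations),
                "mean": st.mean,
                "sd": st.sd,
            }
        )
    return pd.DataFrame(rows)


def render_report(
    summary: VariationSummary,
    comparisons: Iterable[ComparisonResult] = (),
    reference: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> str:
    """Plain-text report: per-session variation tables plus paired tests.

    ``reference`` optionally maps (session, measure) to externally published
    (mean, SD) values; any recomputed statistic that disagrees with its
    reference beyond printing precision is flagged in the report rather
    than silently replaced.
    """
    if not summary.stats:
        raise ValueError("empty summary")
    lines: list[str] = []
    for measure in MEASURES:
        keys = [k for k in summary.stats if k[1] == measure]
        if not keys:
            continue
        lines.append(f"{MEASURE_LABELS[measure]} variation (after - before)")
        for session in SESSIONS:
            if (session, measure) not in summary.stats:
                continue
            st = summary.stats[(session, measure)]
            vals = "  ".join(f"{v:g}" for v in st.variations)
            lines.append(
                f"  {SESSION_LABELS[session]:<30} {vals}  | "
                f"mean {st.mean:.2f}  SD {st.sd:.3f}"
            )
            if reference and (session, measure) in reference:
                ref_mean, ref_sd = reference[(session, measure)]
                notes = []
                if abs(st.mean - ref_mean) > 0.005:
                    notes.append(f"published mean {ref_mean:g}")
                if abs(st.sd - ref_sd) > 0.005:
                    notes.append(
                        f"published SD {ref_sd:g} inconsistent with recomputation"
                    )
                if notes:
                    lines.append(f"    NOTE: {'; '.join(notes)}")
        lines.append("")
    for cmp_res in comparisons:
        lines.append(
            f"Paired comparison ({MEASURE_LABELS[cmp_res.measure]}, "
            f"{cmp_res.method}, n={cmp_res.n}): statistic={cmp_res.statistic:.4f}, "
            f"p={cmp_res.pvalue:.4f}"
            + ("  [significant at alpha=0.05]" if cmp_res.pvalue < 0.05 else "")
        )
    return "\n".join(lines) + "\n"
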