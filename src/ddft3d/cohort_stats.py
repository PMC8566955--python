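"""Cohort-level longitudinal statistics.

Each tendon is scanned at two or more time points; MRI-report and
clinical changes between consecutive scans are coded +1 (improved),
0 (no change), -1 (worse).  This module builds per-tendon transition
records from the cohort table, counts score concordance, and computes
the study-style statistics: Pearson correlation of scores against the
computer-measured change, Shapiro–Wilk normality, Wilcoxon rank-sum
group comparisons, and odds ratios (with Haldane–Anscombe correction and
Woolf confidence intervals) for thickness change beyond a ±1.5 mm
threshold.

Two-sided p-values throughout; no multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

SCORE_VALUES = (-1, 0, 1)

COHORT_COLUMNS = [
    "horse",
    "limb",
    "time",
    "median_thickness_mm",
    "volume_mm3",
    "field_T",
    "mri_score",
    "clinical_score",
]


def example_cohort() -> pd.DataFrame:
    """The bundled example cohort: six horses under repeated foot MRI."""
    with resources.files("ddft3d.data").joinpath("example_cohort.csv").open() as fh:
        return load_cohort(fh)


def load_cohort(path_or_buffer) -> pd.DataFrame:
    """Read a cohort CSV; baseline rows have empty score cells."""
    df = pd.read_csv(path_or_buffer)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    for col in ("mri_score", "clinical_score"):
        df[col] = df[col].astype("Int64")
        bad = df[col].dropna()
        if not bad.isin(SCORE_VALUES).all():
            raise ValueError(f"{col} must be coded -1/0/+1")
    return df


def parse_time_months(label) -> float:
    """Parse scan-time labels like '0', '2 W', '10 M' into months."""
    s = str(label).strip().upper()
    if s.endswith("W"):
        return float(s[:-1]) * 0.25
    if s.endswith("M"):
        return float(s[:-1])
    return float(s)


@dataclass
class TransitionRecord:
    """One consecutive scan pair of one tendon."""

    horse: object
    limb: str
    interval: tuple[str, str]
    mri_score: int
    clinical_score: int
    delta_median_thickness_mm: float
    delta_volume_pct: float
    comparison_min_mm: float | None = None
    comparison_median_mm: float | None = None
    comparison_max_mm: float | None = None
    exceeds_threshold: bool | None = None
    normal: bool = False

    def combined_score(self, policy: str = "mri") -> int | None:
        """Resolve a single score when MRI and clinical disagree.

        ``mri`` / ``clinical`` take that reading; ``concordant-only``
        returns None for discordant transitions.
        """
        if policy == "mri":
            return self.mri_score
        if policy == "clinical":
            return self.clinical_score
        if policy == "concordant-only":
            return self.mri_score if self.mri_score == self.clinical_score else None
        raise ValueError(f"unknown score policy {policy!r}")


def build_transitions(cohort: pd.DataFrame) -> list[TransitionRecord]:
    """One record per consecutive scan pair per tendon.

    Deltas are later minus earlier; volume change is a percentage of the
    earlier volume.  Rows with missing volume or thickness are skipped
    with a warning.
    """
    out: list[TransitionRecord] = []
    for (horse, limb), grp in cohort.groupby(["horse", "limb"], sort=True):
        grp = grp.assign(_months=grp["time"].map(parse_time_months)).sort_values(
            "_months", kind="stable"
        )
        rows = grp.to_dict("records")
        for earlier, later in zip(rows, rows[1:]):
            if any(
                pd.isna(r[c])
                for r in (earlier, later)
                for c in ("median_thickness_mm", "volume_mm3")
            ):
                warnings.warn(
                    f"horse {horse} {limb}: missing thickness/volume, "
                    "transition skipped"
                )
                continue
            if pd.isna(later["mri_score"]) or pd.isna(later["clinical_score"]):
                warnings.warn(
                    f"horse {horse} {limb}: unscored follow-up at "
                    f"{later['time']}"
                )
                continue
            out.append(
                TransitionRecord(
                    horse=horse,
                    limb=limb,
                    interval=(str(earlier["time"]), str(later["time"])),
                    mri_score=int(later["mri_score"]),
                    clinical_score=int(later["clinical_score"]),
                    delta_median_thickness_mm=float(
                        later["median_thickness_mm"] - earlier["median_thickness_mm"]
                    ),
                    delta_volume_pct=float(
                        100.0
                        * (later["volume_mm3"] - earlier["volume_mm3"])
                        / earlier["volume_mm3"]
                    ),
                    normal=bool(earlier.get("normal", 0) or later.get("normal", 0)),
                )
            )
    return out


def pathologic_row_count(cohort: pd.DataFrame) -> int:
    """Tendon-time rows excluding any tendon flagged normal."""
    if "normal" in cohort.columns:
        return int((cohort["normal"].fillna(0) == 0).sum())
    return len(cohort)


def concordance_counts(transitions) -> dict:
    """Partition scored transitions by MRI/clinical agreement.

    Returns counts of both +1, both 0, both -1 and discordant; the four
    classes are exhaustive and mutually exclusive.
    """
    counts = {"both_improved": 0, "both_unchanged": 0, "both_worse": 0,
              "discordant": 0}
    for t in transitions:
        if t.mri_score is None or t.clinical_score is None:
            warnings.warn("unscored transition excluded from concordance")
            continue
        if t.mri_score == t.clinical_score == 1:
            counts["both_improved"] += 1
        elif t.mri_score == t.clinical_score == 0:
            counts["both_unchanged"] += 1
        elif t.mri_score == t.clinical_score == -1:
            counts["both_worse"] += 1
        else:
            counts["discordant"] += 1
    return counts


# ---------------------------------------------------------------------------
# statistics


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation; two-sided p from t with n-2 d.f."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci95: tuple[float, float]
    correction_applied: bool
    table: tuple[float, float, float, float] = field(default=(0, 0, 0, 0))


def odds_ratio(table) -> OddsRatioResult:
    """Odds ratio of a 2x2 table (a, b, c, d) with Woolf 95% CI.

    If any cell is zero, 0.5 is added to every cell (Haldane–Anscombe)
    before both the ratio and the confidence interval.
    """
    a, b, c, d = (float(v) for v in np.asarray(table).ravel())
    if min(a, b, c, d) < 0 or any(v != int(v) for v in (a, b, c, d)):
        raise ValueError("table must hold nonnegative integer counts")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("odds ratio undefined: a row or column sums to zero")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(or_) - 1.96 * se))
    hi = float(np.exp(np.log(or_) + 1.96 * se))
    return OddsRatioResult(float(or_), (lo, hi), corrected, (a, b, c, d))


def thickness_change_table(
    transitions, threshold_mm: float = 1.5, policy: str = "mri"
) -> tuple[int, int, int, int]:
    """2x2 counts for the thickness-change odds ratio.

    Rows: combined score ±1 (changed) versus 0 (static); columns: part
    comparison exceeds ±threshold versus not.  Transitions without a
    comparison summary are excluded.  This table construction is this
    package's declared convention.
    """
    a = b = c = d = 0
    for t in transitions:
        s = t.combined_score(policy)
        if s is None or t.exceeds_threshold is None:
            continue
        if abs(s) == 1:
            if t.exceeds_threshold:
                a += 1
            else:
                b += 1
        else:
            if t.exceeds_threshold:
                c += 1
            else:
                d += 1
    return a, b, c, d


@dataclass
class RankSumResult:
    rank_sum: float
    p: float
    method: str


def compare_groups(a, b) -> RankSumResult:
    """Wilcoxon rank-sum test, two-sided.

    Exact enumeration for small tie-free samples (pooled n <= 20),
    otherwise the normal approximation with midrank ties and continuity
    correction.  Reports the rank sum of the first sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate test: all pooled values identical")
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(pooled) <= 20) and not ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    ranks = stats.rankdata(pooled)
    w = float(ranks[: len(a)].sum())
    return RankSumResult(w, float(res.pvalue), "exact" if exact else "asymptotic")


@dataclass
class NormalityResult:
    w: float
    p: float


def normality(sample) -> NormalityResult:
    """Shapiro–Wilk normality test."""
    sample = np.asarray(sample, float)
    if len(sample) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    res = stats.shapiro(sample)
    return NormalityResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# group summaries


def _median_range(values) -> dict:
    v = np.asarray(values, float)
    from .imaging_io import median_midpoint

    return {
        "median": median_midpoint(v),
        "range": (float(v.min()), float(v.max())),
        "n": int(v.size),
    }


def summarize_outcome_groups(transitions, policy: str = "mri") -> dict:
    """Median and range of volume/thickness change per score group.

    Groups: +1 improved, 0 unchanged, -1 worse by the combined score under
    ``policy``.  Empty groups are omitted with a notice.
    """
    out: dict = {}
    for score, name in ((1, "improved"), (0, "unchanged"), (-1, "worse")):
        grp = [t for t in transitions if t.combined_score(policy) == score]
        if not grp:
            warnings.warn(f"no transitions in group {name}; omitted")
            continue
        entry = {
            "delta_volume_pct": _median_range([t.delta_volume_pct for t in grp]),
            "delta_median_thickness_mm": _median_range(
                [t.delta_median_thickness_mm for t in grp]
            ),
        }
        mins = [t.comparison_min_mm for t in grp if t.comparison_min_mm is not None]
        maxs = [t.comparison_max_mm for t in grp if t.comparison_max_mm is not None]
        if mins:
            entry["comparison_min_mm"] = _median_range(mins)
        if maxs:
            entry["comparison_max_mm"] = _median_range(maxs)
        out[name] = entry
    return out


def correlate_scores(
    transitions,
    column: str = "delta_median_thickness_mm",
    score: str = "mri_score",
) -> CorrelationResult:
    """Correlate change scores against a computer-measured change column."""
    xs = [getattr(t, score) for t in transitions]
    ys = [getattr(t, column) for t in transitions]
    pairs = [(x, y) for x, y in zip(xs, ys) if x is not None and y is not None]
    if len(pairs) < 3:
        raise ValueError("not enough scored transitions")
    x, y = zip(*pairs)
    return pearson_correlation(x, y)
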