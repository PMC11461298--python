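"""Validity and reliability metrics for categorical video ratings.

Ratings are items x raters tables of labels from a fixed set (default
``Normal`` / ``How`` / ``What``: kinematically natural & goal-intact,
kinematically unnatural & goal-intact, and kinematically natural &
goal-violating actions).  The module computes per-rater recognition
accuracy, confusion matrices against the intended category, Fleiss' kappa
for multi-rater agreement, and the one-sample t-test (with Cohen's d and a
95 % CI) comparing accuracy to chance.  Frame/seconds conversion utilities
live here too since reported timings mix both units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_LABELS",
    "RatingMatrix",
    "KappaResult",
    "ChanceTestResult",
    "score_ratings",
    "confusion_matrix",
    "fleiss_kappa",
    "chance_level",
    "one_sample_t",
    "frames_to_seconds",
]

DEFAULT_LABELS = ("Normal", "How", "What")


@dataclass
class RatingMatrix:
    """Items x raters table of categorical ratings, with optional truth labels.

    ``ratings`` is a DataFrame indexed by item (video id) with one column per
    rater; ``truth`` is an optional per-item Series of intended categories.
    """

    ratings: pd.DataFrame
    truth: pd.Series | None = None
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if self.ratings.shape[0] < 1 or self.ratings.shape[1] < 1:
            raise ValueError("rating matrix needs at least one item and one rater")
        label_set = set(self.labels)
        observed = set(self.ratings.values.ravel())
        bad = observed - label_set - {None} - {np.nan}
        if bad:
            raise ValueError(f"ratings outside label set {self.labels}: {sorted(bad)}")
        if self.truth is not None:
            self.truth = self.truth.reindex(self.ratings.index)
            bad_truth = set(self.truth.dropna()) - label_set
            if bad_truth:
                raise ValueError(f"truth labels outside label set: {sorted(bad_truth)}")

    @property
    def n_items(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    def counts(self) -> pd.DataFrame:
        """Per-item counts of each label (items x categories)."""
        out = pd.DataFrame(0, index=self.ratings.index, columns=list(self.labels))
        for lab in self.labels:
            out[lab] = (self.ratings == lab).sum(axis=1)
        return out

    @classmethod
    def from_long(
        cls,
        table: pd.DataFrame,
        labels: Sequence[str] = DEFAULT_LABELS,
    ) -> "RatingMatrix":
        """Build from a tidy table with columns video_id, rater_id, response
        and optionally truth."""
        required = {"video_id", "rater_id", "response"}
        if not required <= set(table.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        wide = table.pivot(index="video_id", columns="rater_id", values="response")
        truth = None
        if "truth" in table.columns:
            truth = table.drop_duplicates("video_id").set_index("video_id")["truth"]
            truth = truth.reindex(wide.index)
        return cls(ratings=wide, truth=truth, labels=tuple(labels))

    @classmethod
    def read_csv(cls, path: str | Path, labels: Sequence[str] = DEFAULT_LABELS) -> "RatingMatrix":
        return cls.from_long(pd.read_csv(Path(path), dtype=str), labels=labels)

    def to_long(self) -> pd.DataFrame:
        """Tidy long-format export (video_id, rater_id, response[, truth]) so
        downstream stats packages can fit their own models."""
        long = (
            self.ratings.stack()
            .rename("response")
            .rename_axis(["video_id", "rater_id"])
            .reset_index()
        )
        if self.truth is not None:
            long = long.merge(
                self.truth.rename("truth").rename_axis("video_id").reset_index(),
                on="video_id",
            )
        return long


def score_ratings(ratings: RatingMatrix) -> pd.DataFrame:
    """Per-rater recognition accuracy: correct counts and percentages."""
    if ratings.truth is None or ratings.truth.isna().any():
        raise ValueError("scoring requires a truth label for every item")
    correct = ratings.ratings.eq(ratings.truth, axis=0)
    counts = correct.sum(axis=0)
    return pd.DataFrame(
        {
            "n_correct": counts.astype(int),
            "pct_correct": 100.0 * counts / ratings.n_items,
        }
    ).rename_axis("rater_id")


def confusion_matrix(
    ratings: RatingMatrix, per_item: bool = False
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Counts of (true category, assigned category) pairs.

    Rows are the intended category, columns the assigned one; row sums equal
    raters x items of that category.  With ``per_item`` a matrix per video is
    returned (these sum to the overall matrix).
    """
    if ratings.truth is None or ratings.truth.isna().any():
        raise ValueError("confusion matrix requires a truth label for every item")
    labels = list(ratings.labels)

    def one(items: pd.Index) -> pd.DataFrame:
        mat = pd.DataFrame(0, index=labels, columns=labels)
        sub = ratings.ratings.loc[items]
        truth = ratings.truth.loc[items]
        for true_lab in labels:
            rows = sub.loc[truth == true_lab]
            if rows.empty:
                continue
            assigned = rows.stack().value_counts()
            for lab, count in assigned.items():
                mat.loc[true_lab, lab] += int(count)
        return mat.rename_axis(index="true", columns="assigned")

    if per_item:
        return {item: one(pd.Index([item])) for item in ratings.ratings.index}
    return one(ratings.ratings.index)


@dataclass(frozen=True)
class KappaResult:
    """Fleiss' kappa with its ingredients.

    ``per_item_agreement`` holds P_i for each item, ``category_proportions``
    the marginal p_j per category, ``mean_agreement`` P-bar and
    ``expected_agreement`` the chance level P-bar_e.  ``undefined`` flags the
    degenerate case P-bar_e == 1 (all ratings in a single category), where
    kappa has no value; batch runs can then skip rather than crash.
    """

    kappa: float
    per_item_agreement: np.ndarray = field(repr=False)
    category_proportions: np.ndarray
    mean_agreement: float
    expected_agreement: float
    undefined: bool = False


def fleiss_kappa(ratings: RatingMatrix) -> KappaResult:
    """Chance-corrected multi-rater agreement for categorical labels.

    Requires every item rated by the same number n >= 2 of raters.  With
    n_ij the count of raters assigning category j to item i:

        P_i   = (sum_j n_ij^2 - n) / (n (n - 1))
        p_j   = sum_i n_ij / (N n)
        kappa = (P-bar - P-bar_e) / (1 - P-bar_e),  P-bar_e = sum_j p_j^2
    """
    counts = ratings.counts().to_numpy(dtype=float)
    per_item_n = counts.sum(axis=1)
    n = per_item_n[0]
    if not np.all(per_item_n == n):
        raise ValueError("Fleiss' kappa requires the same number of ratings per item")
    if n < 2:
        raise ValueError("Fleiss' kappa requires at least 2 raters per item")
    n_items = counts.shape[0]
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_j = counts.sum(axis=0) / (n_items * n)
    p_bar = float(p_i.mean())
    p_e = float((p_j**2).sum())
    if p_e >= 1.0 - 1e-15:
        return KappaResult(
            kappa=float("nan"),
            per_item_agreement=p_i,
            category_proportions=p_j,
            mean_agreement=p_bar,
            expected_agreement=p_e,
            undefined=True,
        )
    return KappaResult(
        kappa=(p_bar - p_e) / (1.0 - p_e),
        per_item_agreement=p_i,
        category_proportions=p_j,
        mean_agreement=p_bar,
        expected_agreement=p_e,
    )


def chance_level(n_items: int, k_categories: int) -> float:
    """Expected number of correct classifications under uniform guessing."""
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    if k_categories < 2:
        raise ValueError(f"need at least 2 categories, got {k_categories}")
    return n_items / k_categories


@dataclass(frozen=True)
class ChanceTestResult:
    """One-sample t-test against a reference value.

    ``cohens_d`` is the one-sample effect size (mean - mu0) / SD; the CI is
    the two-sided 95 % interval for the mean.  ``degenerate`` flags zero
    sample variance, where t is unbounded.
    """

    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    cohens_d: float
    mean: float
    sd: float
    n: int
    mu0: float
    degenerate: bool = False


def one_sample_t(
    values: Sequence[float] | None = None,
    mu0: float = 0.0,
    *,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    confidence: float = 0.95,
) -> ChanceTestResult:
    """One-sample t-test, from raw values or from (mean, SD, n) summaries.

    The summary entry point lets reported statistics be checked without the
    raw per-rater data.  SD is the sample standard deviation (ddof = 1).
    """
    if values is not None:
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least 2 observations")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        n = int(arr.size)
    if mean is None or sd is None or n is None:
        raise ValueError("provide raw values or all of mean, sd, n")
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    if sd == 0.0:
        return ChanceTestResult(
            t=math.inf if mean != mu0 else 0.0,
            df=df,
            p=0.0 if mean != mu0 else 1.0,
            ci_low=mean,
            ci_high=mean,
            cohens_d=math.inf if mean != mu0 else 0.0,
            mean=mean,
            sd=sd,
            n=n,
            mu0=mu0,
            degenerate=True,
        )
    se = sd / math.sqrt(n)
    t = (mean - mu0) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    return ChanceTestResult(
        t=t,
        df=df,
        p=p,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        cohens_d=(mean - mu0) / sd,
        mean=mean,
        sd=sd,
        n=n,
        mu0=mu0,
    )


def frames_to_seconds(frames: float, fps: float) -> float:
    """Convert a frame count to seconds at a given frame rate.

    E.g. a 3-frame discrepancy at 60 frames/s is a 50 ms trigger jitter.
    """
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    return frames / fps
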