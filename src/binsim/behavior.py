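"""Synthetic listeners and descriptive statistics.

Human responses are emulated by listeners with a logistic psychometric
function: the probability of reporting a keyword correctly at an effective
SNR x is p = 1 / (1 + exp(-slope * (x - SRT))), keyword counts are binomial
draws, and a sentence scores correct only when every keyword does.  The
normal-hearing (NH) group sits at a lower SRT than the hearing-impaired
(HI) group, so simulated condition means reproduce the qualitative group
ordering of the study without claiming its human percentages.

Descriptive analysis mirrors the study's reporting pipeline: scores are
averaged over the repetitions of each condition per subject before any
comparison; effect sizes are Cohen's d on the subject means; and pairwise
p-values carry a Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .stimuli import TrialSpec

__all__ = [
    "SyntheticListener",
    "TrialResult",
    "make_listener_group",
    "respond",
    "fit_psychometric",
    "results_frame",
    "summarize",
    "cohens_d",
    "pairwise_bonferroni",
]

#: group-level psychometric defaults (dB): the HI group needs a higher SNR
#: for the same intelligibility, NH/HI separation ~6 dB with 1.5-dB
#: individual spread; the slope 0.5/dB gives ~12.5 %-points/dB at the SRT.
GROUP_SRT_DB = {"NH": 0.0, "HI": 6.0}
LISTENER_SD_DB = 1.5
DEFAULT_SLOPE = 0.5
KEYWORDS_PER_SENTENCE = 5


@dataclass(frozen=True)
class SyntheticListener:
    """A logistic-psychometric stand-in for one participant."""

    group: str
    srt_offset: float
    slope: float = DEFAULT_SLOPE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUP_SRT_DB:
            raise ValueError("group must be 'NH' or 'HI'")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


@dataclass(frozen=True)
class TrialResult:
    trial: TrialSpec
    keywords_total: int
    keywords_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.keywords_correct <= self.keywords_total:
            raise ValueError("keyword counts out of range")

    @property
    def sentence_correct(self) -> int:
        return int(self.keywords_correct == self.keywords_total)


def make_listener_group(group: str, n: int, seed: int = 0) -> list[SyntheticListener]:
    """Draw ``n`` listeners around the group mean SRT."""
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, {"NH": 0, "HI": 1}[group]])
    )
    return [
        SyntheticListener(
            group=group,
            srt_offset=float(GROUP_SRT_DB[group] + LISTENER_SD_DB * rng.standard_normal()),
            seed=int(rng.integers(2**31 - 1)),
        )
        for _ in range(n)
    ]


def psychometric(effective_snr: float, srt: float, slope: float) -> float:
    return 1.0 / (1.0 + math.exp(-slope * (effective_snr - srt)))


def respond(
    listener: SyntheticListener,
    trial: TrialSpec,
    effective_snr: float,
    keywords_total: int = KEYWORDS_PER_SENTENCE,
) -> TrialResult:
    """One scored trial: binomial keyword draws at the psychometric p.

    Deterministic given the listener seed and the trial's own seeds.
    """
    if not math.isfinite(effective_snr):
        raise ValueError("effective SNR must be finite")
    p = psychometric(effective_snr, listener.srt_offset, listener.slope)
    rng = np.random.default_rng(
        np.random.SeedSequence([listener.seed, trial.seeds[0], trial.repetition])
    )
    correct = int(rng.binomial(keywords_total, p))
    return TrialResult(trial=trial, keywords_total=keywords_total,
                       keywords_correct=correct)


def fit_psychometric(snr_db: np.ndarray, correct: np.ndarray, total: np.ndarray):
    """Maximum-likelihood logistic fit of keyword proportions vs SNR.

    Returns ``(srt, slope, srt_se, slope_se)`` where the SRT is the 50%
    point -b0/b1.  Raises ``ValueError`` for degenerate data (fewer than
    two SNR levels, or all-correct / all-wrong responses, which make the
    likelihood unbounded).
    """
    snr_db = np.asarray(snr_db, dtype=float)
    correct = np.asarray(correct, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.unique(snr_db).size < 2:
        raise ValueError("need responses at two or more SNR levels")
    if correct.sum() == 0 or correct.sum() == total.sum():
        raise ValueError("degenerate responses: psychometric fit is unbounded")
    exog = sm.add_constant(snr_db)
    model = sm.GLM(np.column_stack([correct, total - correct]), exog,
                   family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as err:  # perfect separation and friends
        raise ValueError(f"psychometric fit failed: {err}") from err
    b0, b1 = res.params
    if b1 <= 0:
        raise ValueError("fitted slope is non-positive")
    srt = -b0 / b1
    cov = res.cov_params()
    grad = np.array([-1.0 / b1, b0 / b1**2])
    srt_se = float(np.sqrt(grad @ cov @ grad))
    return float(srt), float(b1), srt_se, float(np.sqrt(cov[1, 1]))


def results_frame(results: list[TrialResult], listener_id) -> pd.DataFrame:
    """Long-format results table (one row per scored trial)."""
    rows = []
    for r in results:
        t = r.trial
        rows.append({
            "listener": listener_id, "group": t.group, "room": t.room,
            "snr": t.snr, "config": t.config, "processing": t.processing,
            "repetition": t.repetition, "keywords_total": r.keywords_total,
            "keywords_correct": r.keywords_correct,
            "sentence_correct": r.sentence_correct,
        })
    return pd.DataFrame(rows)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("Cohen's d needs at least two observations per group")
    sp = math.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def _subject_means(df: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    # average over the repetitions of each condition per subject first
    cell = ["listener", "group", "room", "snr", "config", "processing"]
    per_subject = df.groupby(cell, as_index=False)["sentence_correct"].mean()
    return per_subject.groupby(["listener"] + factors, as_index=False)["sentence_correct"].mean()


def summarize(df: pd.DataFrame, factor: str = "config") -> dict:
    """Condition means, Cohen's d and Bonferroni-adjusted pairwise p-values.

    ``df`` is a long-format results table; scores are first averaged over
    repetitions per subject and condition.  Returns a dict with the
    per-level means table and a pairwise-comparison table.
    """
    means = (
        df.groupby(["listener", "group", "room", "snr", "config", "processing"],
                   as_index=False)["sentence_correct"].mean()
        .groupby(["group", "room", "snr", "config", "processing"], as_index=False)
        ["sentence_correct"].mean()
    )
    per = _subject_means(df, [factor])
    comparisons = pairwise_bonferroni(per, factor, value="sentence_correct")
    return {"condition_means": means, "pairwise": comparisons}


def pairwise_bonferroni(df: pd.DataFrame, factor: str,
                        value: str = "sentence_correct") -> pd.DataFrame:
    """All pairwise Welch t-tests on subject means, Bonferroni-adjusted."""
    levels = sorted(df[factor].unique())
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa = df.loc[df[factor] == a, value].to_numpy()
        xb = df.loc[df[factor] == b, value].to_numpy()
        if xa.size < 2 or xb.size < 2:
            rows.append({"a": a, "b": b, "d": float("nan"),
                         "p_raw": float("nan"), "p_adj": float("nan"),
                         "flag": "single-subject cell"})
            continue
        t = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({
            "a": a, "b": b, "d": cohens_d(xa, xb),
            "p_raw": float(t.pvalue), "p_adj": float(min(1.0, m * t.pvalue)),
            "flag": "",
        })
    return pd.DataFrame(rows)
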