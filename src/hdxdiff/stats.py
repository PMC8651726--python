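"""Significance testing of differential deuterium uptake between two states.

The procedure derives one global confidence interval per state pair from the
replicate scatter of triplicated timepoints: per-(peptide, timepoint) sample
SDs are root-mean-square averaged within each state, pooled across the two
states in quadrature, and scaled by the two-tailed Student-t critical value
at 98% confidence with n-1 degrees of freedom (6.965 for triplicates).  A
per-peptide, per-timepoint difference in mean uptake is called significant
when its magnitude exceeds that interval.  No multiple-testing correction is
applied; the fixed CI is deliberately conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import PeptideRecord

__all__ = [
    "SignificanceThreshold",
    "DifferenceRecord",
    "ComparisonResult",
    "sd_state",
    "sd_pool",
    "confidence_interval",
    "t_multiplier",
    "compute_threshold",
    "compare_states",
]


def t_multiplier(n: int = 3, confidence: float = 0.98) -> float:
    """Two-tailed Student-t critical value with n-1 degrees of freedom."""
    if n < 2:
        raise ValueError(f"need at least 2 replicates, got n={n}")
    return float(_sps.t.ppf(1.0 - (1.0 - confidence) / 2.0, df=n - 1))


@dataclass(frozen=True)
class SignificanceThreshold:
    """The global CI for one state pair and its ingredients, all in Da."""

    sd_state_a: float
    sd_state_b: float
    sd_pool: float
    n: int
    t_multiplier: float
    ci: float


@dataclass(frozen=True)
class DifferenceRecord:
    """Per-peptide, per-timepoint uptake difference with its verdict.

    ``delta`` is mean(test state) − mean(reference state); negative delta
    means the test state takes up less deuterium, i.e. protection.
    ``delta_rfu`` is the same difference normalized to the peptide's
    maximally labelled uptake, when a control is available.
    """

    peptide: PeptideRecord
    timepoint: float
    delta: float
    significant: bool
    sign: str  # "protection" | "deprotection" | "none"
    delta_rfu: float | None = None


@dataclass(frozen=True)
class ComparisonResult:
    records: list[DifferenceRecord]
    threshold: SignificanceThreshold
    state_ref: str
    state_test: str
    only_in_ref: list[tuple[int, int]]
    only_in_test: list[tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "start": r.peptide.start,
                "end": r.peptide.end,
                "sequence": r.peptide.sequence,
                "exposure_s": r.timepoint,
                "delta_Da": r.delta,
                "delta_rfu": r.delta_rfu,
                "significant": r.significant,
                "sign": r.sign,
            }
            for r in sorted(self.records, key=lambda r: (r.peptide.start, r.peptide.end, r.timepoint))
        ]
        return pd.DataFrame(rows)


def sd_state(replicate_sds: list[float] | np.ndarray) -> float:
    """Root-mean-square average of per-(peptide, timepoint) replicate SDs.

    The divisor is the number of pooled SDs: peptides considered times the
    number of timepoints run in triplicate.
    """
    sds = np.asarray(replicate_sds, dtype=float)
    if sds.size == 0:
        raise ValueError("no replicate SDs supplied (no triplicated timepoints?)")
    return float(np.sqrt(np.mean(sds**2)))


def sd_pool(sd_a: float, sd_b: float) -> float:
    """Pooled SD for the difference between two states (quadrature sum)."""
    return math.hypot(sd_a, sd_b)


def confidence_interval(sd_pooled: float, n: int = 3, confidence: float = 0.98) -> float:
    """Half-width of the zero-centred CI: ``t * sd_pool / sqrt(n)``.

    At the defaults (triplicates, 98% two-tailed, 2 degrees of freedom) the
    multiplier is 6.965.
    """
    return t_multiplier(n, confidence) * sd_pooled / math.sqrt(n)


def _replicate_sds(frame: pd.DataFrame, state: str, min_replicates: int) -> np.ndarray:
    sub = frame[frame["state"] == state]
    grouped = sub.groupby(["start", "end", "exposure_s"])["uptake_Da"]
    counts = grouped.count()
    sds = grouped.std(ddof=1)
    return sds[counts >= min_replicates].to_numpy()


def compute_threshold(
    frame: pd.DataFrame,
    state_ref: str,
    state_test: str,
    n: int = 3,
    confidence: float = 0.98,
    min_replicates: int = 3,
) -> SignificanceThreshold:
    """Derive the global CI for a state pair from triplicated timepoints.

    Only (peptide, timepoint) groups measured with at least ``min_replicates``
    replicates contribute SDs; singleton timepoints contribute differences
    downstream but no variance information.
    """
    sd_a = sd_state(_replicate_sds(frame, state_ref, min_replicates))
    sd_b = sd_state(_replicate_sds(frame, state_test, min_replicates))
    pooled = sd_pool(sd_a, sd_b)
    t = t_multiplier(n, confidence)
    return SignificanceThreshold(sd_a, sd_b, pooled, n, t, t * pooled / math.sqrt(n))


def compare_states(
    frame: pd.DataFrame,
    state_ref: str,
    state_test: str,
    threshold: SignificanceThreshold | None = None,
    uptake_max: dict[tuple[int, int], float] | None = None,
    n: int = 3,
    confidence: float = 0.98,
) -> ComparisonResult:
    """Per-peptide, per-timepoint differential uptake between two states.

    ``delta = mean(test) - mean(ref)`` over available replicates for every
    (peptide, timepoint) shared by both states; significance is
    ``|delta| > ci``.  Peptides observed in only one state are reported
    separately rather than dropped silently (strong binding can suppress a
    peptide's signal in one state entirely).  Swapping the states negates
    every delta and leaves the significance set unchanged.
    """
    for s in (state_ref, state_test):
        if s not in set(frame["state"]):
            raise ValueError(f"state {s!r} not present in the uptake table")
    if threshold is None:
        threshold = compute_threshold(frame, state_ref, state_test, n=n, confidence=confidence)

    peptide_info: dict[tuple[int, int], PeptideRecord] = {}
    for row in frame.drop_duplicates(["start", "end"]).itertuples(index=False):
        key = (int(row.start), int(row.end))
        peptide_info[key] = PeptideRecord(str(row.protein), str(row.sequence), *key)

    means = (
        frame[frame["state"].isin([state_ref, state_test])]
        .groupby(["start", "end", "state", "exposure_s"])["uptake_Da"]
        .mean()
        .unstack("state")
    )
    peps_ref = {(s, e) for (s, e, _), row in means.iterrows() if not np.isnan(row.get(state_ref, np.nan))}
    peps_test = {(s, e) for (s, e, _), row in means.iterrows() if not np.isnan(row.get(state_test, np.nan))}
    shared = peps_ref & peps_test
    if not shared:
        raise ValueError(f"states {state_ref!r} and {state_test!r} share no peptides")

    records: list[DifferenceRecord] = []
    for (start, end, exposure), row in means.iterrows():
        key = (int(start), int(end))
        m_ref, m_test = row.get(state_ref, np.nan), row.get(state_test, np.nan)
        if np.isnan(m_ref) or np.isnan(m_test):
            continue
        delta = float(m_test - m_ref)
        significant = abs(delta) > threshold.ci
        sign = "none" if not significant else ("protection" if delta < 0 else "deprotection")
        delta_rfu = None
        if uptake_max is not None and key in uptake_max and uptake_max[key] > 0:
            delta_rfu = delta / uptake_max[key]
        records.append(
            DifferenceRecord(peptide_info[key], float(exposure), delta, significant, sign, delta_rfu)
        )
    return ComparisonResult(
        records=records,
        threshold=threshold,
        state_ref=state_ref,
        state_test=state_test,
        only_in_ref=sorted(peps_ref - shared),
        only_in_test=sorted(peps_test - shared),
    )
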