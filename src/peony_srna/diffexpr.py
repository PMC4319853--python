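"""Differential expression of miRNA counts between two libraries.

Counts are normalized to transcripts per million (TPM = count / total
clean reads x 10^6); the fold-change is log2(treatment / control) with
a small pseudo-TPM guarding zeros.  Significance uses the
Audic-Claverie exact test for a count observed in two libraries of
known sizes: conditional on x reads in library 1, the probability of
observing y reads in library 2 is

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

computed in log-space via log-gamma.  The lower and upper cumulative
tails C(y'<=y|x) and D(y'>=y|x) yield a two-sided p-value
min(1, 2 min(C, D)); the infinite upper tail is evaluated as the
complement of the finite lower sum, so C + D - p(y|x) = 1 identically.
Benjamini-Hochberg adjustment and the significance call
(p_adj < 0.01 and |log2FC| > 1) follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountPair",
    "DEResult",
    "tpm",
    "log2fc",
    "ac_pvalue",
    "ac_interval",
    "adjust_pvalues",
    "call_de",
    "de_table",
]

DEFAULT_PSEUDO_TPM = 0.01


@dataclass(frozen=True)
class CountPair:
    """Counts of one miRNA in two libraries with their total clean reads."""

    mirna_id: str
    x: int  # library 1 (control, CK)
    y: int  # library 2 (treatment, TR)
    n1: int
    n2: int

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be nonnegative")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")
        if self.x > self.n1 or self.y > self.n2:
            raise ValueError("count exceeds its library total")


@dataclass
class DEResult:
    mirna_id: str
    x: int
    y: int
    tpm_ck: float
    tpm_tr: float
    log2fc: float
    p_point: float
    p_lower: float  # C(y' <= y | x)
    p_upper: float  # D(y' >= y | x)
    p_two_sided: float
    p_adjusted: float = math.nan
    significant: bool = False
    direction: str = "unchanged"


def tpm(count: int, total_clean_reads: int) -> float:
    """Transcripts per million: count / total x 10^6."""
    if total_clean_reads <= 0:
        raise ValueError("total clean reads must be positive")
    return count / total_clean_reads * 1e6


def log2fc(tpm_tr: float, tpm_ck: float, pseudo: float = DEFAULT_PSEUDO_TPM) -> float:
    """log2((treatment + pseudo) / (control + pseudo))."""
    if pseudo < 0 or (pseudo == 0 and (tpm_tr <= 0 or tpm_ck <= 0)):
        raise ValueError("pseudo must be positive when either arm is zero")
    return math.log2((tpm_tr + pseudo) / (tpm_ck + pseudo))


def _log_pmf(x: int, yv: np.ndarray, log_r: float) -> np.ndarray:
    # log p(y|x) with r = N2/N1
    return (yv * log_r + gammaln(x + yv + 1) - gammaln(x + 1) - gammaln(yv + 1)
            - (x + yv + 1) * np.log1p(np.exp(log_r)))


def ac_pvalue(pair: CountPair) -> tuple[float, float, float, float]:
    """Audic-Claverie point probability, tails and two-sided p-value.

    Returns (p_point, C, D, p_two_sided) where C sums p(y'|x) for
    y' <= y, D for y' >= y (as 1 minus the finite sum below y), and
    p_two_sided = min(1, 2 min(C, D)).
    """
    x, y = pair.x, pair.y
    log_r = math.log(pair.n2) - math.log(pair.n1)
    yv = np.arange(0, y + 1, dtype=np.float64)
    probs = np.exp(_log_pmf(x, yv, log_r))
    p_point = float(probs[-1])
    c = float(probs.sum())
    d = 1.0 - (c - p_point)
    c = min(c, 1.0)
    d = min(max(d, p_point), 1.0)
    p_two = min(1.0, 2.0 * min(c, d))
    return p_point, c, d, p_two


def ac_interval(x: int, n1: int, n2: int, epsilon: float = 0.05,
                max_y: int | None = None) -> tuple[int, int]:
    """Equal-tail interval [y_min, y_max] for y given x at level epsilon:
    the smallest y_min with C(y<=y_min|x) > epsilon/2 and the smallest
    y_max with D(y>=y_max+1|x) < epsilon/2 (utility; not part of the
    significance path)."""
    log_r = math.log(n2) - math.log(n1)
    if max_y is None:
        max_y = int(10 + 10 * (x + 1) * max(1.0, n2 / n1))
    yv = np.arange(0, max_y + 1, dtype=np.float64)
    cdf = np.cumsum(np.exp(_log_pmf(x, yv, log_r)))
    y_min = int(np.searchsorted(cdf, epsilon / 2.0, side="left"))
    y_max = int(np.searchsorted(cdf, 1.0 - epsilon / 2.0, side="left"))
    return y_min, y_max


def adjust_pvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment."""
    if len(pvalues) == 0:
        return []
    return list(multipletests(list(pvalues), method="fdr_bh")[1])


def call_de(pairs: Sequence[CountPair], p_thresh: float = 0.01,
            lfc_thresh: float = 1.0, pseudo: float = DEFAULT_PSEUDO_TPM,
            adjust: bool = True) -> list[DEResult]:
    """Full differential-expression pass over a list of count pairs.

    significant iff p_adjusted < p_thresh and |log2fc| > lfc_thresh
    (both strict); direction follows the sign of the fold-change.
    With ``adjust=False`` the raw two-sided p is used unadjusted.
    """
    results: list[DEResult] = []
    for pair in pairs:
        t_ck = tpm(pair.x, pair.n1)
        t_tr = tpm(pair.y, pair.n2)
        lfc = log2fc(t_tr, t_ck, pseudo)
        p_point, c, d, p_two = ac_pvalue(pair)
        results.append(DEResult(pair.mirna_id, pair.x, pair.y, t_ck, t_tr,
                                lfc, p_point, c, d, p_two))
    adjusted = (adjust_pvalues([r.p_two_sided for r in results]) if adjust
                else [r.p_two_sided for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
        r.significant = p_adj < p_thresh and abs(r.log2fc) > lfc_thresh
        if r.significant:
            r.direction = "up" if r.log2fc > 0 else "down"
    return results


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mirna": r.mirna_id, "x": r.x, "y": r.y,
          "tpm_ck": r.tpm_ck, "tpm_tr": r.tpm_tr, "log2fc": r.log2fc,
          "p": r.p_two_sided, "p_adj": r.p_adjusted,
          "significant": r.significant, "direction": r.direction}
         for r in results])
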