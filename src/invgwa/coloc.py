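"""Approximate-Bayes-factor colocalization of two association score profiles.

Per-variant evidence uses the Wakefield approximate Bayes factor computed from
the effect estimate and its standard error under a Gaussian effect prior with
standard deviation ``W``:

    log ABF = 1/2 log(1 - r) + 1/2 Z^2 r,   r = W^2 / (W^2 + se^2), Z = beta/se.

Windows are scored under the five single-causal-variant hypotheses — H0 no
association, H1/H2 association with one trait only, H3 two distinct causal
variants, H4 one shared causal variant — with all configuration sums taken in
log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import DataValidationError, GWAResult

__all__ = ["wakefield_log_abf", "coloc_abf", "sliding_coloc", "ColocWindow"]

HYPOTHESES = ("PP_H0", "PP_H1", "PP_H2", "PP_H3", "PP_H4")


def wakefield_log_abf(
    beta: np.ndarray | float, se: np.ndarray | float, prior_sd: float = 0.15
) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor for single-variant association."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DataValidationError("standard errors must be positive")
    if prior_sd <= 0:
        raise DataValidationError("prior_sd must be positive")
    V = se**2
    r = prior_sd**2 / (prior_sd**2 + V)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * z**2 * r
    return out if out.ndim else float(out)


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal within precision."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    beta1: np.ndarray,
    se1: np.ndarray,
    beta2: np.ndarray,
    se2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd: float = 0.15,
) -> dict[str, float]:
    """Posterior probabilities PP_H0..PP_H4 for one variant window.

    Both traits must be scored on the same variant list. Hypothesis sums are
    computed in log space: H1 = p1 * sum_i ABF1_i, H2 analogous,
    H4 = p12 * sum_i ABF1_i ABF2_i, and H3 = p1 p2 (sum_i ABF1_i sum_j ABF2_j
    - sum_i ABF1_i ABF2_i), normalized against H0 = 1.
    """
    b1, b2 = np.asarray(beta1, float), np.asarray(beta2, float)
    if b1.shape != b2.shape or b1.size == 0:
        raise DataValidationError("traits must share a non-empty variant list")
    l1 = np.asarray(wakefield_log_abf(b1, se1, prior_sd))
    l2 = np.asarray(wakefield_log_abf(b2, se2, prior_sd))
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + _log_diff_exp(s1 + s2, s12),
            np.log(p12) + s12,
        ]
    )
    norm = logsumexp(lh[np.isfinite(lh)])
    pp = np.where(np.isfinite(lh), np.exp(lh - norm), 0.0)
    return dict(zip(HYPOTHESES, pp.tolist()))


@dataclass
class ColocWindow:
    arm: str
    start: int
    end: int  # exclusive
    n_variants: int
    probabilities: dict[str, float] | None  # None when insufficient data

    @property
    def insufficient(self) -> bool:
        return self.probabilities is None


def sliding_coloc(
    result1: GWAResult,
    result2: GWAResult,
    window_bp: int = 10_000,
    step_bp: int = 5_000,
    min_variants: int = 5,
    arm_lengths: dict[str, int] | None = None,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd: float = 0.15,
) -> list[ColocWindow]:
    """Colocalize two score profiles over tiled windows per arm.

    Windows start at 1 and advance by ``step_bp``; only full windows are
    emitted (``[start, start + window_bp)``, inclusive start / exclusive end).
    Variants are matched by id across the two results; windows with fewer
    than ``min_variants`` shared variants carry no probabilities.
    """
    t1 = result1.table.set_index("id")
    t2 = result2.table.set_index("id")
    shared = t1.index.intersection(t2.index)
    if shared.empty:
        raise DataValidationError("no shared variants between the two scans")
    t1, t2 = t1.loc[shared], t2.loc[shared]
    windows: list[ColocWindow] = []
    for arm in pd.unique(t1["arm"]):
        mask = (t1["arm"] == arm).to_numpy()
        pos = t1.loc[mask, "pos"].to_numpy()
        length = (
            arm_lengths[arm] if arm_lengths and arm in arm_lengths else int(pos.max())
        )
        b1 = t1.loc[mask, "beta"].to_numpy()
        s1 = t1.loc[mask, "se"].to_numpy()
        b2 = t2.loc[mask, "beta"].to_numpy()
        s2 = t2.loc[mask, "se"].to_numpy()
        start = 1
        while start + window_bp - 1 <= length:
            sel = (pos >= start) & (pos < start + window_bp)
            n = int(sel.sum())
            if n >= min_variants:
                pp = coloc_abf(
                    b1[sel], s1[sel], b2[sel], s2[sel],
                    p1=p1, p2=p2, p12=p12, prior_sd=prior_sd,
                )
            else:
                pp = None
            windows.append(
                ColocWindow(
                    arm=str(arm), start=start, end=start + window_bp,
                    n_variants=n, probabilities=pp,
                )
            )
            start += step_bp
    return windows


def coloc_table(windows: list[ColocWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        row = {"arm": w.arm, "start": w.start, "end": w.end, "n_variants": w.n_variants,
               "insufficient": w.insufficient}
        row.update(w.probabilities or {h: np.nan for h in HYPOTHESES})
        rows.append(row)
    return pd.DataFrame(rows)
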