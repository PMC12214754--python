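"""Unit-inclusion screening for pose/viewpoint encoding analyses.

Implements the five inclusion criteria applied jointly ("AND") to each unit:
(a) responsivity -- split-plot ANOVA of baseline vs response window with the
stimulus as a between-trial factor; (b) spike-count stability -- the slope of
trial-to-trial count variance on mean count ("Fano slope") below 4; (c) a
maximum mean net rate above 5 spikes/s; (d) stimulus selectivity by
Kruskal-Wallis; (e) split-half reliability (Spearman-Brown corrected) above
0.5 -- plus a Body Selectivity Index screen (BSI >= 0.33 with a significant
response in the category test).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# responsivity: split-plot (mixed) ANOVA
# ---------------------------------------------------------------------------

def _splitplot_anova_many(
    baseline: np.ndarray, response: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced split-plot ANOVA, vectorized over units.

    Inputs are (..., n_trials, n_stimuli): each presentation (trial of a
    stimulus) is a subject measured in two windows (the repeated factor);
    the stimulus is the between-subject factor.  Returns p-values for the
    window main effect and the window x stimulus interaction, both tested
    against the window-by-subject-within-stimulus error term.
    """
    b = np.asarray(baseline, dtype=float)
    r = np.asarray(response, dtype=float)
    if b.shape != r.shape:
        raise ValueError("baseline and response must have matched trial structure")
    n, a = b.shape[-2], b.shape[-1]  # trials per stimulus, stimuli
    if a < 2 or n < 2:
        raise ValueError("need >= 2 stimuli and >= 2 trials per stimulus")
    p = 2  # within-subject levels

    y = np.stack([b, r], axis=-1)                  # (..., n, a, p)
    grand = y.sum(axis=(-3, -2, -1))
    C = grand**2 / (a * n * p)
    ss_total = (y**2).sum(axis=(-3, -2, -1)) - C

    A_i = y.sum(axis=(-3, -1))                     # (..., a) stimulus totals
    S_ij = y.sum(axis=-1)                          # (..., n, a) subject totals
    B_k = y.sum(axis=(-3, -2))                     # (..., p) window totals
    AB_ik = y.sum(axis=-3)                         # (..., a, p)

    ss_A = (A_i**2).sum(axis=-1) / (n * p) - C
    ss_subj = (S_ij**2).sum(axis=(-2, -1)) / p - (A_i**2).sum(axis=-1) / (n * p)
    ss_B = (B_k**2).sum(axis=-1) / (a * n) - C
    ss_AB = (
        (AB_ik**2).sum(axis=(-2, -1)) / n
        - (A_i**2).sum(axis=-1) / (n * p)
        - (B_k**2).sum(axis=-1) / (a * n)
        + C
    )
    ss_err = ss_total - ss_A - ss_subj - ss_B - ss_AB

    df_err = a * (n - 1) * (p - 1)
    ms_err = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f_B = (ss_B / (p - 1)) / ms_err
        f_AB = (ss_AB / ((a - 1) * (p - 1))) / ms_err
    p_B = stats.f.sf(f_B, p - 1, df_err)
    p_AB = stats.f.sf(f_AB, (a - 1) * (p - 1), df_err)
    return p_B, p_AB


def responsivity_anova(
    baseline_rates: np.ndarray, response_rates: np.ndarray
) -> tuple[float, float]:
    """Split-plot ANOVA of window (repeated) by stimulus (between-trial).

    Returns ``(p_window, p_interaction)``; a unit counts as responsive when
    either p-value is below the threshold (0.05 by default downstream).
    """
    p_b, p_ab = _splitplot_anova_many(baseline_rates, response_rates)
    return float(p_b), float(p_ab)


# ---------------------------------------------------------------------------
# Fano slope
# ---------------------------------------------------------------------------

def fano_factor(response_rates: np.ndarray, window_s: float = 0.2) -> float:
    """OLS slope of per-stimulus spike-count variance on mean spike count.

    Rates are converted to counts over the response window.  For a Poisson
    unit the slope is ~1; the screening threshold (slope < 4) discards
    units with unstable, super-Poisson trial-to-trial variability.
    """
    counts = np.asarray(response_rates, dtype=float) * window_s
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    if np.unique(mean).size < 3:
        raise ValueError("need >= 3 distinct stimulus means for a defined slope")
    slope = np.polyfit(mean, var, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------

def selectivity_test(response_rates: np.ndarray) -> float:
    """Kruskal-Wallis test of the stimulus effect on response-window rates."""
    r = np.asarray(response_rates, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need >= 2 trials per stimulus")
    return float(stats.kruskal(*[r[:, s] for s in range(r.shape[1])]).pvalue)


# ---------------------------------------------------------------------------
# split-half reliability
# ---------------------------------------------------------------------------

def spearman_brown(r: float) -> float:
    """Boost a half-data correlation to full-data length: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability_matrix(
    rates: np.ndarray, n_splits: int = 100, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Spearman-Brown corrected split-half reliability, vectorized over units.

    ``rates`` is (n_units, n_trials, n_stimuli).  Per split, the trials of
    each stimulus are independently halved at random (odd counts: the extra
    trial goes to the first half); the per-half stimulus means are Pearson
    correlated across stimuli and Spearman-Brown corrected; the result is
    the average over ``n_splits`` splits.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 2:
        rates = rates[None]
    n_units, n_trials, n_stim = rates.shape
    if n_trials < 2:
        raise ValueError("need >= 2 trials per stimulus for a split-half")
    if rng is None:
        rng = np.random.default_rng()
    h1 = (n_trials + 1) // 2

    out = np.zeros(n_units)
    for _ in range(n_splits):
        order = rng.random((n_units, n_trials, n_stim)).argsort(axis=1)
        shuffled = np.take_along_axis(rates, order, axis=1)
        m1 = shuffled[:, :h1].mean(axis=1)
        m2 = shuffled[:, h1:].mean(axis=1)
        m1 = m1 - m1.mean(axis=1, keepdims=True)
        m2 = m2 - m2.mean(axis=1, keepdims=True)
        denom = np.sqrt((m1**2).sum(axis=1) * (m2**2).sum(axis=1))
        if np.any(denom == 0):
            raise FloatingPointError("constant half-means: correlation undefined")
        r = (m1 * m2).sum(axis=1) / denom
        out += 2.0 * r / (1.0 + r)
    return out / n_splits


def split_half_reliability(
    response_rates: np.ndarray, n_splits: int = 100, seed: int = 0
) -> float:
    """Single-unit convenience wrapper around the vectorized computation."""
    return float(
        split_half_reliability_matrix(
            np.asarray(response_rates)[None], n_splits=n_splits,
            rng=np.random.default_rng(seed),
        )[0]
    )


# ---------------------------------------------------------------------------
# Body Selectivity Index
# ---------------------------------------------------------------------------

def compute_bsi(category_rates: dict) -> float:
    """Body Selectivity Index from the category test.

    BSI = (net_bodies - net_nonbodies) / (|net_bodies| + |net_nonbodies|),
    where each term is the mean net (response - baseline) rate over the 20
    body movies or the 40 face + object movies.  0.33 corresponds to a
    twofold stronger net response to bodies.
    """
    labels = np.asarray(category_rates["labels"])
    net = (
        np.asarray(category_rates["response_rates"], float).mean(axis=0)
        - np.asarray(category_rates["baseline_rates"], float).mean(axis=0)
    )
    body = net[labels == "body"].mean()
    nonbody = net[labels != "body"].mean()
    denom = abs(body) + abs(nonbody)
    if denom == 0:
        raise ZeroDivisionError("BSI undefined: zero net rates in both categories")
    return float((body - nonbody) / denom)


# ---------------------------------------------------------------------------
# the joint screen
# ---------------------------------------------------------------------------

@dataclass
class SelectionThresholds:
    """Screening thresholds; defaults are the standard criteria."""

    responsivity_alpha: float = 0.05
    fano_max: float = 4.0
    min_net_rate: float = 5.0     # spikes/s, max over stimuli of mean net rate
    selectivity_alpha: float = 0.05
    min_reliability: float = 0.5
    min_bsi: float = 0.33
    bsi_alpha: float = 0.05
    n_reliability_splits: int = 100


@dataclass
class SelectionReport:
    """Per-criterion outcomes for one unit; ``passed`` is the AND of all."""

    unit_id: str
    responsivity_p: float
    interaction_p: float
    fano: float
    max_net_rate: float
    selectivity_p: float
    reliability: float
    bsi: float | None
    bsi_response_p: float | None
    criteria: dict = field(default_factory=dict)
    passed: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update({f"pass_{k}": v for k, v in d.pop("criteria").items()})
        return d


def select_units(
    units, thresholds: SelectionThresholds | None = None, seed: int = 0
) -> list[SelectionReport]:
    """Apply the joint inclusion screen to a collection of units.

    Each unit must expose ``response_rates`` and ``baseline_rates``
    (n_trials x n_stimuli) and optionally ``category_rates``; units without
    a category test skip the BSI criteria.
    """
    th = thresholds or SelectionThresholds()
    reports = []
    for i, unit in enumerate(units):
        resp, base = unit.response_rates, unit.baseline_rates
        p_win, p_int = responsivity_anova(base, resp)
        fano = fano_factor(resp)
        max_net = float((resp.mean(axis=0) - base.mean(axis=0)).max())
        p_sel = selectivity_test(resp)
        rel = split_half_reliability(
            resp, n_splits=th.n_reliability_splits, seed=seed + i
        )
        criteria = {
            "responsivity": bool(p_win < th.responsivity_alpha
                                 or p_int < th.responsivity_alpha),
            "fano": bool(fano < th.fano_max),
            "net_rate": bool(max_net > th.min_net_rate),
            "selectivity": bool(p_sel < th.selectivity_alpha),
            "reliability": bool(rel > th.min_reliability),
        }
        bsi = bsi_p = None
        if getattr(unit, "category_rates", None) is not None:
            cat = unit.category_rates
            bsi = compute_bsi(cat)
            cp_win, cp_int = responsivity_anova(
                cat["baseline_rates"], cat["response_rates"]
            )
            bsi_p = min(cp_win, cp_int)
            criteria["bsi"] = bool(bsi >= th.min_bsi and bsi_p < th.bsi_alpha)
        reports.append(
            SelectionReport(
                unit_id=getattr(unit, "unit_id", str(i)),
                responsivity_p=p_win, interaction_p=p_int, fano=fano,
                max_net_rate=max_net, selectivity_p=p_sel, reliability=rel,
                bsi=bsi, bsi_response_p=bsi_p, criteria=criteria,
                passed=all(criteria.values()),
            )
        )
    return reports


def selection_frame(reports: list[SelectionReport]) -> pd.DataFrame:
    """Tabulate selection reports (one row per unit)."""
    return pd.DataFrame([r.to_dict() for r in reports])
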