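"""Methylation x coverage classification of CpGs inside peaks, and the
normal-approximation probability that a CpG belongs to its assigned
methylation cluster.

Group definitions (read literally from the legend wording, boundary values
going to the named inclusive interval):

* G1 — low methylation (beta < 0.20), high coverage (> 50 reads)
* G2 — low methylation, low coverage (5 to 50 reads)
* G3 — intermediate methylation (0.20 <= beta <= 0.80), low coverage
* G4 — high methylation (beta > 0.80), low coverage
* UNGROUPED — beta >= 0.20 with coverage > 50 (a combination the assay
  essentially never produces, accessibility and methylation being
  anticorrelated)
* EXCLUDED — coverage below the minimum of 5 reads

The cluster-membership probability treats the observed beta b from n reads
as approximately normal with mean b and variance b(1-b)/(n-1), and reports
P(b < C_h) - P(b < C_l) for the assigned cluster's methylation bounds
(C_l, C_h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import CpGSite

GROUP_LABELS = ("G1", "G2", "G3", "G4", "UNGROUPED", "EXCLUDED")

#: methylation bounds (C_l, C_h) per assigned group
GROUP_BOUNDS = {
    "G1": (0.0, 0.2),
    "G2": (0.0, 0.2),
    "G3": (0.2, 0.8),
    "G4": (0.8, 1.0),
}


@dataclass
class GroupingThresholds:
    meth_low: float = 0.20
    meth_high: float = 0.80
    cov_min: int = 5
    cov_high: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.meth_low < self.meth_high < 1):
            raise ValueError("require 0 < meth_low < meth_high < 1")
        if not (0 < self.cov_min <= self.cov_high):
            raise ValueError("require 0 < cov_min <= cov_high")


def assign_group(
    site: CpGSite, thresholds: Optional[GroupingThresholds] = None
) -> str:
    """Assign the methylation/coverage group label of one CpG site."""
    t = thresholds or GroupingThresholds()
    cov = site.coverage
    if cov < t.cov_min:
        return "EXCLUDED"
    beta = site.beta
    low_cov = cov <= t.cov_high  # "5 to 50 reads" is inclusive
    if beta < t.meth_low:
        return "G2" if low_cov else "G1"
    if not low_cov:
        return "UNGROUPED"
    return "G3" if beta <= t.meth_high else "G4"


def _phi(x: float) -> float:
    """Standard normal CDF via erf (no table lookups, no Monte-Carlo)."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def cluster_membership_probability(
    b: float, n: int, c_l: float, c_h: float
) -> float:
    """Probability that a CpG's sampling-mean beta lies within its
    cluster's bounds: Phi((C_h - b)/s) - Phi((C_l - b)/s) with
    s = sqrt(b(1-b)/(n-1)).

    Degenerate spread (b in {0, 1}) collapses the distribution onto b:
    the probability is 1 if b lies in [C_l, C_h) and 0 otherwise.
    """
    if n < 2:
        raise ValueError("need n >= 2 reads for the variance formula")
    if c_l >= c_h:
        raise ValueError("require C_l < C_h")
    if not (0.0 <= b <= 1.0):
        raise ValueError("beta must be in [0, 1]")
    s = math.sqrt(b * (1.0 - b) / (n - 1))
    if s == 0.0:
        return 1.0 if c_l <= b < c_h else 0.0
    return _phi((c_h - b) / s) - _phi((c_l - b) / s)


def site_membership_probability(
    site: CpGSite, label: Optional[str] = None,
    thresholds: Optional[GroupingThresholds] = None,
) -> float:
    """Membership probability of a site in its (assigned) group."""
    label = label or assign_group(site, thresholds)
    if label not in GROUP_BOUNDS:
        return float("nan")
    c_l, c_h = GROUP_BOUNDS[label]
    return cluster_membership_probability(site.beta, site.coverage, c_l, c_h)


def group_summary(
    sites: Iterable[CpGSite],
    thresholds: Optional[GroupingThresholds] = None,
) -> pd.DataFrame:
    """Per-site table of group labels and membership probabilities.

    One row per site with beta, coverage, label and, for grouped sites,
    the cluster-membership probability.  Use
    :func:`group_counts` for the per-label tally.
    """
    rows = []
    for s in sites:
        label = assign_group(s, thresholds)
        prob = (
            site_membership_probability(s, label, thresholds)
            if label in GROUP_BOUNDS
            else float("nan")
        )
        rows.append(
            {
                "contig": s.contig,
                "pos0": s.pos0,
                "beta": s.beta,
                "coverage": s.coverage,
                "label": label,
                "membership_probability": prob,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos0",
            "beta",
            "coverage",
            "label",
            "membership_probability",
        ],
    )


def group_counts(summary: pd.DataFrame) -> pd.DataFrame:
    """Counts and beta/coverage medians per group label."""
    rows = []
    for label in GROUP_LABELS:
        sub = summary[summary["label"] == label]
        probs = sub["membership_probability"].dropna() if len(sub) else sub
        rows.append(
            {
                "label": label,
                "n": len(sub),
                "median_beta": float(sub["beta"].median()) if len(sub) else float("nan"),
                "median_coverage": float(sub["coverage"].median()) if len(sub) else float("nan"),
                "median_membership_probability": (
                    float(probs.median()) if len(probs) else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
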