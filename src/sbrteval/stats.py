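"""Paired nonparametric technique comparison.

Per metric: a Kruskal-Wallis omnibus test across techniques, all pairwise
two-sided Wilcoxon matched-pairs signed-rank tests, and Benjamini-Hochberg
FDR control at q = 0.05 over the pairwise family.  Median paired
differences accompany every comparison so "significant and consistent"
claims can be checked against the direction of the effect.

The rank tests wrap scipy.stats; BH wraps statsmodels.  Conventions:

* degenerate all-identical input -> H = 0, p = 1 (omnibus) and p = 1
  (Wilcoxon with all-zero differences);
* zero paired differences are dropped before ranking (classic Wilcoxon);
* the exact two-sided Wilcoxon null distribution is used for n <= 12
  without ties, the normal approximation with continuity and tie
  correction otherwise;
* the BH family defaults to the pairwise comparisons within one metric,
  configurable to a single global family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "compare_pipeline",
    "StatResult",
]

EXACT_WILCOXON_MAX_N = 12


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across groups.

    All values identical across all groups is reported as (0, 1): no
    evidence of any location difference, rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def wilcoxon_signed_rank(differences: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test on paired
    differences.  Returns ``(W, p)`` with ``W = min(T+, T-)``.

    Zeros are dropped; all differences zero -> (0, 1).
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one pair")
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    no_ties = np.unique(np.abs(d)).size == d.size
    if d.size <= EXACT_WILCOXON_MAX_N and no_ties:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method="exact")
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(adjusted p-values, reject flags)``; a hypothesis is
    rejected iff its adjusted p-value is <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class StatResult:
    """Output of the full comparison pipeline."""

    omnibus: pd.DataFrame   # metric, n_techniques, n_patients, H, p
    pairwise: pd.DataFrame  # metric, tech_a, tech_b, n, W, p_raw, p_adj,
    #                         significant, median_diff
    q: float = 0.05
    skipped_metrics: list[str] = field(default_factory=list)


def _paired_block(df: pd.DataFrame, techniques: list[str]):
    """Pivot one metric's rows to a complete patient x technique block,
    or None if any pair is missing."""
    wide = df.pivot_table(index="patient", columns="technique", values="value",
                          aggfunc="first")
    if not set(techniques).issubset(wide.columns):
        return None
    wide = wide[techniques]
    if wide.isna().any().any():
        return None
    return wide


def compare_pipeline(
    cohort: pd.DataFrame,
    q: float = 0.05,
    family: str = "per_metric",  # "per_metric" | "global"
    omnibus_gate: bool = False,
) -> StatResult:
    """Run the full per-metric comparison on a long-format cohort table.

    ``cohort`` needs columns ``patient``, ``technique``, ``metric``,
    ``value``.  Metrics with incomplete pairing are skipped with a
    warning.  With ``omnibus_gate=True`` pairwise significance is only
    granted when the omnibus p-value itself falls below ``q`` (strict
    gatekeeping); by default both levels are reported without gating.
    """
    required = {"patient", "technique", "metric", "value"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    if family not in ("per_metric", "global"):
        raise ValueError(f"unknown BH family {family!r}")

    techniques = sorted(cohort["technique"].unique())
    if len(techniques) < 2:
        raise ValueError("need at least two techniques")
    metrics = sorted(cohort["metric"].unique())

    omni_rows, pair_rows, skipped = [], [], []
    for metric in metrics:
        block = _paired_block(cohort[cohort["metric"] == metric], techniques)
        if block is None:
            warnings.warn(f"metric {metric!r} skipped: incomplete paired design")
            skipped.append(metric)
            continue
        h, p_omni = kruskal_wallis([block[t].to_numpy() for t in techniques])
        omni_rows.append(
            dict(metric=metric, n_techniques=len(techniques),
                 n_patients=len(block), H=h, p=p_omni)
        )
        for ta, tb in itertools.combinations(techniques, 2):
            diff = block[tb].to_numpy() - block[ta].to_numpy()
            w, p_raw = wilcoxon_signed_rank(diff)
            pair_rows.append(
                dict(metric=metric, tech_a=ta, tech_b=tb, n=len(diff), W=w,
                     p_raw=p_raw, median_diff=float(np.median(diff)),
                     omnibus_p=p_omni)
            )

    omnibus = pd.DataFrame(
        omni_rows, columns=["metric", "n_techniques", "n_patients", "H", "p"]
    )
    pairwise = pd.DataFrame(
        pair_rows,
        columns=["metric", "tech_a", "tech_b", "n", "W", "p_raw",
                 "median_diff", "omnibus_p"],
    )
    if len(pairwise):
        p_adj = np.full(len(pairwise), np.nan)
        reject = np.zeros(len(pairwise), dtype=bool)
        if family == "global":
            p_adj, reject = bh_adjust(pairwise["p_raw"].to_numpy(), q)
        else:
            for metric in pairwise["metric"].unique():
                idx = pairwise.index[pairwise["metric"] == metric].to_numpy()
                p_adj[idx], reject[idx] = bh_adjust(
                    pairwise.loc[idx, "p_raw"].to_numpy(), q
                )
        if omnibus_gate:
            reject &= pairwise["omnibus_p"].to_numpy() <= q
        pairwise["p_adj"] = p_adj
        pairwise["significant"] = reject
    else:
        pairwise["p_adj"] = np.nan
        pairwise["significant"] = pd.Series(dtype=bool)
    return StatResult(omnibus=omnibus, pairwise=pairwise, q=q,
                      skipped_metrics=skipped)
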