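"""Significance machinery for differential splicing.

Differential cotranscriptional splicing between two conditions is tested
per intron with Pearson chi-square tests on 2×2 spliced/unspliced tables,
one per replicate *pair* (replicate i of condition A against replicate i of
condition B).  The per-pair p-values are combined conservatively by taking
their maximum — an intron is only as significant as its least-concordant
replicate pair — and Benjamini-Hochberg adjustment is applied across
introns within one contrast.  A change is called when both an effect-size
cutoff (|Δ metric| ≥ delta_min) and the adjusted p-value cutoff are met.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

COMBINERS = ("max", "fisher")


def chisq_2x2(
    a_spliced: int,
    a_unspliced: int,
    b_spliced: int,
    b_unspliced: int,
    continuity_correction: bool = False,
) -> float:
    """Pearson chi-square p-value on a 2×2 spliced/unspliced table.

    No continuity correction by default.  A degenerate table in which one
    column total is zero (e.g. no spliced read in either condition) means
    the two proportions are identical, and is returned as p = 1.0 — it
    carries no evidence of a difference.  A zero *row* total (an empty
    replicate) leaves the comparison undefined and returns NaN.
    """
    table = np.array(
        [[a_spliced, a_unspliced], [b_spliced, b_unspliced]], dtype=float
    )
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table[0].sum() == 0 or table[1].sum() == 0:
        return float("nan")
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    _, p, _, _ = sps.chi2_contingency(table, correction=continuity_correction)
    return float(p)


def replicate_chisq(
    a_counts: Sequence[tuple[int, int]],
    b_counts: Sequence[tuple[int, int]],
    combine: str = "max",
    continuity_correction: bool = False,
) -> tuple[list[float], float]:
    """Paired-replicate chi-square: replicate i of A versus replicate i of B.

    Parameters
    ----------
    a_counts, b_counts
        Equal-length sequences of (n_spliced, n_unspliced) per replicate.
    combine
        ``max`` (default, conservative: every pair must concur) or
        ``fisher`` (Fisher's combination).

    Returns the per-pair p-value list (NaN where a pair was undefined) and
    the combined p over the defined pairs (NaN when no pair is defined).
    """
    if len(a_counts) != len(b_counts):
        raise ValueError("conditions must have the same number of replicates")
    if combine not in COMBINERS:
        raise ValueError(f"combine must be one of {COMBINERS}")
    pvals = [
        chisq_2x2(a_s, a_u, b_s, b_u, continuity_correction)
        for (a_s, a_u), (b_s, b_u) in zip(a_counts, b_counts)
    ]
    valid = [p for p in pvals if not np.isnan(p)]
    if not valid:
        logger.warning("no valid replicate pair; intron dropped")
        return pvals, float("nan")
    if combine == "max":
        combined = max(valid)
    else:
        combined = float(sps.combine_pvalues(valid, method="fisher").pvalue)
    return pvals, float(combined)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving, capped at 1; NaN entries are excluded from the
    adjustment and reinserted as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def flag_significant(
    metric_a: pd.DataFrame,
    metric_b: pd.DataFrame,
    test_results: pd.DataFrame,
    delta_min: float = 0.1,
    alpha: float = 0.05,
    key: str = "intron_id",
    value: str = "value",
) -> pd.DataFrame:
    """Call significant metric changes from combined per-intron p-values.

    ``metric_a``/``metric_b`` hold the per-intron metric (columns ``key``
    and ``value``); ``test_results`` holds columns ``key`` and ``p``
    (combined p per intron).  BH adjustment is applied across the introns
    present in ``test_results``.  Significant means |Δ| ≥ delta_min and
    adjusted p < alpha, with Δ = metric_B − metric_A; the direction column
    reads ``more_splicing`` for Δ > 0 and ``more_retention`` for Δ < 0.
    """
    for name, frame, cols in (
        ("metric_a", metric_a, (key, value)),
        ("metric_b", metric_b, (key, value)),
        ("test_results", test_results, (key, "p")),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"{name} missing columns {sorted(missing)}")
    a = metric_a.set_index(key)[value]
    b = metric_b.set_index(key)[value]
    keys = list(test_results[key])
    missing = [k for k in keys if k not in a.index or k not in b.index]
    if missing:
        raise ValueError(f"introns missing from metric tables: {missing[:10]}")
    out = test_results[[key, "p"]].copy()
    out["delta"] = b.loc[keys].to_numpy() - a.loc[keys].to_numpy()
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (np.abs(out["delta"]) >= delta_min) & (out["p_adj"] < alpha)
    out["direction"] = np.select(
        [out["delta"] > 0, out["delta"] < 0],
        ["more_splicing", "more_retention"],
        default="none",
    )
    return out


def differential_splicing(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    delta_min: float = 0.1,
    alpha: float = 0.05,
    combine: str = "max",
) -> pd.DataFrame:
    """End-to-end contrast from per-replicate spliced/unspliced counts.

    Each input frame has columns intron_id, replicate, n_spliced,
    n_unspliced.  Only introns present in both conditions with the same
    replicate labels are tested.  Returns the :func:`flag_significant`
    table plus the pooled metric per condition (metric = spliced fraction).
    """
    for name, frame in (("counts_a", counts_a), ("counts_b", counts_b)):
        missing = {"intron_id", "replicate", "n_spliced", "n_unspliced"} - set(
            frame.columns
        )
        if missing:
            raise ValueError(f"{name} missing columns {sorted(missing)}")
    common = sorted(
        set(counts_a["intron_id"]) & set(counts_b["intron_id"])
    )
    rows = []
    metric_rows_a, metric_rows_b = [], []
    for intron in common:
        ga = counts_a[counts_a["intron_id"] == intron].set_index("replicate")
        gb = counts_b[counts_b["intron_id"] == intron].set_index("replicate")
        reps = sorted(set(ga.index) & set(gb.index))
        if not reps:
            continue
        a_c = [(int(ga.loc[r, "n_spliced"]), int(ga.loc[r, "n_unspliced"])) for r in reps]
        b_c = [(int(gb.loc[r, "n_spliced"]), int(gb.loc[r, "n_unspliced"])) for r in reps]
        _, combined = replicate_chisq(a_c, b_c, combine=combine)
        if np.isnan(combined):
            continue
        rows.append({"intron_id": intron, "p": combined})
        tot_a = sum(s + u for s, u in a_c)
        tot_b = sum(s + u for s, u in b_c)
        metric_rows_a.append(
            {"intron_id": intron, "value": sum(s for s, _ in a_c) / tot_a if tot_a else np.nan}
        )
        metric_rows_b.append(
            {"intron_id": intron, "value": sum(s for s, _ in b_c) / tot_b if tot_b else np.nan}
        )
    if not rows:
        return pd.DataFrame(
            columns=["intron_id", "p", "delta", "p_adj", "significant", "direction"]
        )
    return flag_significant(
        pd.DataFrame(metric_rows_a),
        pd.DataFrame(metric_rows_b),
        pd.DataFrame(rows),
        delta_min=delta_min,
        alpha=alpha,
    )
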