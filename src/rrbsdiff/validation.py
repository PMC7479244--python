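"""Pyrosequencing-validation statistics.

Replicate consolidation with the >5-point inconsistency rule, per-DMR
RRBS-vs-pyrosequencing Spearman concordance, and age-stratified two-group
permutation tests per CpG.

Pooling rule for more than two replicates: keep the largest subset with
pairwise range <= 5 points, breaking ties toward including earlier replicates,
and average the kept subset.  Samples with no consistent pair are flagged
missing.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PermutationResult

MAX_REPLICATE_DIFF = 5.0


def _best_consistent_subset(values: list[float], max_diff: float) -> list[int] | None:
    """Indices (original order) of the largest subset with range <= max_diff;
    ties broken toward the earliest replicates.  None if no pair qualifies."""
    n = len(values)
    best: list[int] | None = None
    for size in range(n, 1, -1):
        candidates = [
            list(c)
            for c in combinations(range(n), size)
            if max(values[i] for i in c) - min(values[i] for i in c) <= max_diff
        ]
        if candidates:
            best = min(candidates)  # lexicographically earliest index set
            break
    return best


def consolidate_replicates(
    measurements: pd.DataFrame, max_diff: float = MAX_REPLICATE_DIFF
) -> pd.DataFrame:
    """Collapse replicate pyrosequencing percentages to one value per CpG per
    sample.

    ``measurements`` columns: region, cpg_index, sample_id, replicate,
    percentage.  Output columns: region, cpg_index, sample_id, percentage
    (NaN if no consistent replicate set), n_replicates, consistent (bool).
    A single replicate is flagged and excluded (NaN).
    """
    out = []
    for (region, cpg, sid), grp in measurements.groupby(
        ["region", "cpg_index", "sample_id"], sort=True
    ):
        vals = grp.sort_values("replicate")["percentage"].tolist()
        if len(vals) < 2:
            out.append((region, cpg, sid, np.nan, len(vals), False))
            continue
        keep = _best_consistent_subset(vals, max_diff)
        if keep is None:
            out.append((region, cpg, sid, np.nan, len(vals), False))
        else:
            mean = float(np.mean([vals[i] for i in keep]))
            out.append((region, cpg, sid, mean, len(vals), True))
    return pd.DataFrame(
        out,
        columns=["region", "cpg_index", "sample_id", "percentage", "n_replicates", "consistent"],
    )


def spearman_concordance(
    rrbs_means: pd.DataFrame, pyro_means: pd.DataFrame, min_pairs: int = 5
) -> pd.DataFrame:
    """Per-region Spearman rank correlation between RRBS and pyrosequencing
    per-sample DMR means.

    Both inputs have columns ``region, sample_id, percentage``; the RRBS value
    per sample is the mean methylation of the DMCs composing the DMR.  Ties are
    handled by midranks; a constant vector yields a missing rho.
    """
    rows = []
    merged = rrbs_means.merge(
        pyro_means, on=["region", "sample_id"], suffixes=("_rrbs", "_pyro")
    ).dropna(subset=["percentage_rrbs", "percentage_pyro"])
    for region, grp in merged.groupby("region", sort=True):
        n = len(grp)
        if n < min_pairs:
            rows.append((region, n, np.nan, np.nan))
            continue
        x = grp["percentage_rrbs"].to_numpy()
        y = grp["percentage_pyro"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((region, n, np.nan, np.nan))
            continue
        rho, p = sps.spearmanr(x, y)
        rows.append((region, n, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["region", "n_samples", "rho", "p"])


def _mean_diff(values: np.ndarray, mask1: np.ndarray) -> float:
    return float(values[mask1].mean() - values[~mask1].mean())


def stratified_permutation_test(
    values,
    group_labels,
    strata,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-group Monte-Carlo permutation test with stratified label shuffling.

    ``group_labels`` are two levels (e.g. HM/MM); ``strata`` (e.g. age) are
    permuted within — every draw preserves the per-stratum group counts, which
    keeps the test valid when the strata carry a main effect that is unevenly
    distributed between the groups.  Statistic: difference of group means
    (first-sorted label minus the other).  Two-sided add-one p-value by
    doubling the smaller tail, capped at 1.  Strata containing a single group
    are dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    strata = np.asarray(strata)
    if not (len(values) == len(group_labels) == len(strata)):
        raise ValueError("values, group_labels and strata must align")
    levels = sorted(set(group_labels))
    if len(levels) != 2:
        raise ValueError("exactly two group labels required")
    keep = np.ones(len(values), dtype=bool)
    for s in np.unique(strata):
        in_s = strata == s
        if len(set(group_labels[in_s])) < 2:
            import warnings

            warnings.warn(f"stratum {s!r} contains a single group; dropped", stacklevel=2)
            keep &= ~in_s
    values, group_labels, strata = values[keep], group_labels[keep], strata[keep]
    if len(values) == 0 or len(set(group_labels)) < 2:
        raise ValueError("no stratum contains both groups")

    mask1 = group_labels == levels[0]
    observed = _mean_diff(values, mask1)
    rng = np.random.default_rng(seed)
    strat_ids = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    chunk = 2000
    done = 0
    count_ge = 0
    count_le = 0
    n_total = len(values)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm_mask = np.empty((m, n_total), dtype=bool)
        for idx in strat_ids:
            # shuffle labels within the stratum only: per-stratum counts fixed
            sub = np.broadcast_to(mask1[idx], (m, len(idx)))
            order = np.argsort(rng.random((m, len(idx))), axis=1)
            perm_mask[:, idx] = np.take_along_axis(np.ascontiguousarray(sub), order, axis=1)
        assert (perm_mask.sum(axis=1) == mask1.sum()).all()
        n1 = mask1.sum()
        s1 = (values * perm_mask).sum(axis=1)
        stats = s1 / n1 - (values.sum() - s1) / (n_total - n1)
        count_ge += int((stats >= observed - 1e-15).sum())
        count_le += int((stats <= observed + 1e-15).sum())
        done += m
    p_ge = (1 + count_ge) / (n_perm + 1)
    p_le = (1 + count_le) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_ge, p_le))
    return PermutationResult(statistic=observed, n_perm=n_perm, p_value=p, seed=seed)


def unstratified_permutation_test(
    values, group_labels, n_perm: int = 100_000, seed: int | None = None
) -> PermutationResult:
    """Same two-group test with unrestricted label shuffling (no strata) — the
    comparator that loses level control under a stratum main effect."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    return stratified_permutation_test(
        values, group_labels, np.zeros(len(values), dtype=int), n_perm=n_perm, seed=seed
    )


def per_cpg_group_tests(
    consolidated: pd.DataFrame,
    sheet: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Age-stratified HM-vs-MM permutation test at every region CpG of a
    consolidated pyrosequencing table; significance marked at p < 0.05."""
    meta = sheet.set_index("sample_id")
    rows = []
    for (region, cpg), grp in consolidated.dropna(subset=["percentage"]).groupby(
        ["region", "cpg_index"], sort=True
    ):
        sids = grp["sample_id"]
        res = stratified_permutation_test(
            grp["percentage"].to_numpy(),
            meta.loc[sids, "group"].to_numpy(),
            meta.loc[sids, "age"].to_numpy(),
            n_perm=n_perm,
            seed=seed,
        )
        rows.append(
            {
                "region": region,
                "cpg_index": cpg,
                "n_samples": len(grp),
                "mean_diff_hm_minus_mm": res.statistic,
                "p": res.p_value,
                "significant": res.p_value < 0.05,
            }
        )
    return pd.DataFrame(rows)
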