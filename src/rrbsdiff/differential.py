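"""Differential methylation: beta-binomial Wald tests, covariate-weighted FDR,
DMC thresholds and DMR assembly.

Model
-----
For CpG *i* and group *g* with replicate counts ``(x_gj, n_gj)`` the methylated
proportion is modelled beta-binomially: ``x_gj ~ BetaBin(n_gj, p_gi, phi_i)``,
where ``phi_i`` is the biological (between-bull) overdispersion.  ``phi_i`` is
estimated per site by method of moments from the within-group replicate
variances and shrunk toward a genome-wide dispersion-mean trend (the average
raw dispersion within quantile bins of pooled methylation level) with an
empirical-Bayes weight that grows with the per-site degrees of freedom.  The
group difference is tested with a Wald statistic on the coverage-weighted
group proportions, with the variance evaluated at the pooled (null)
proportion; two-sided p-values come from the normal tail.  This is a
deliberately simplified re-implementation of the dispersion-shrinkage
beta-binomial Wald approach popularised for two-group bisulfite designs — no
smoothing, no covariates in the mean model.

FDR adjustment is a native, simplified independent-hypothesis-weighting
scheme: the covariate (per-site mean methylation over both groups) is cut into
quantile bins, each bin receives a weight proportional to its estimated
non-null fraction (Storey's pi0 at lambda = 0.5), weights are normalised to
unit mean, and Benjamini-Hochberg runs on ``p / weight``.  With one bin this
reduces exactly to Benjamini-Hochberg.

A DMC must be covered in at least 4 bulls per group, have an adjusted p-value
below 0.1 (strict) and an absolute group difference of at least 10 percentage
points; a DMR is a maximal chain of 3 or more DMCs with consecutive gaps of at
most 100 bp.  The difference is oriented group1 - group2 (group1 the HM-like
group), so positive differences mean hypermethylation in group1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CountMatrix

PHI_MIN, PHI_MAX = 1e-6, 0.999


@dataclass(frozen=True)
class ComparisonSpec:
    """Thresholds and group labels for one pairwise comparison."""

    group1: str
    group2: str
    min_samples_per_group: int = 4
    alpha_adj: float = 0.1
    min_diff: float = 10.0  # percentage points
    ihw_alpha: float = 0.05
    ihw_bins: int = 10
    paired: bool = False  # bookkeeping only; the test is the same two-group test

    def __post_init__(self):
        if self.group1 == self.group2:
            raise ValueError("comparison groups must be distinct")
        if self.alpha_adj <= 0 or self.min_diff <= 0 or self.ihw_alpha <= 0:
            raise ValueError("thresholds must be positive")


# ------------------------------------------------------------------ estimation


def _group_moments(meth: np.ndarray, total: np.ndarray):
    """Per-site pooled proportion, replicate count, between-replicate variance
    and mean inverse coverage for one group (missing cells: total == 0)."""
    present = total > 0
    m = present.sum(axis=1)
    tot = total.sum(axis=1)
    phat = np.where(tot > 0, meth.sum(axis=1) / np.maximum(tot, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(present, meth / np.maximum(total, 1), np.nan)
        pbar = np.nanmean(np.where(present, prop, np.nan), axis=1)
        resid = np.where(present, (prop - pbar[:, None]) ** 2, 0.0)
        var = resid.sum(axis=1) / np.maximum(m - 1, 1)
        inv_n = np.where(present, 1.0 / np.maximum(total, 1), 0.0).sum(axis=1) / np.maximum(m, 1)
    return phat, pbar, m, tot, var, inv_n


def estimate_dispersion_shrunk(
    meth1, total1, meth2, total2, prior_weight: float = 8.0, trend_bins: int = 4
) -> np.ndarray:
    """Method-of-moments beta-binomial dispersion per site, shrunk toward a
    dispersion-mean trend.

    The raw estimate solves ``var(p_hat) = p(1-p) (phi + (1-phi) * mean(1/n))``
    within each group and combines the two groups by degrees of freedom.  The
    empirical-Bayes prior mean is estimated *locally*: sites are cut into
    ``trend_bins`` quantile bins of pooled methylation level and each bin
    averages its (unfloored) raw estimates — averaging before flooring keeps
    the prior unbiased even though roughly half the per-site moment estimates
    fall below zero by sampling noise, and the binning captures the strong
    dependence of biological overdispersion on methylation level.  Shrinkage
    is the df-weighted convex combination ``(w * max(phi_raw, 0) + w0 *
    phi_bar(level)) / (w + w0)`` with ``w0 = prior_weight``; the result is
    clipped to [1e-6, 0.999].
    """
    raw_num = None
    df_tot = None
    for meth, total in ((meth1, total1), (meth2, total2)):
        _, pbar, m, _, var, inv_n = _group_moments(meth, total)
        pq = pbar * (1 - pbar)
        df = np.maximum(m - 1, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = (var / np.where(pq > 0, pq, np.nan) - inv_n) / np.maximum(1 - inv_n, 1e-9)
        phi = np.where(np.isfinite(phi) & (df > 0), phi, 0.0)
        contrib = df * phi
        raw_num = contrib if raw_num is None else raw_num + contrib
        df_tot = df if df_tot is None else df_tot + df
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(df_tot > 0, raw_num / np.maximum(df_tot, 1), np.nan)
    usable = df_tot > 0
    n = len(raw)

    # local prior: mean raw dispersion per pooled-methylation quantile bin
    x_all = meth1.sum(axis=1) + meth2.sum(axis=1)
    n_all = total1.sum(axis=1) + total2.sum(axis=1)
    level = np.where(n_all > 0, x_all / np.maximum(n_all, 1), 0.5)
    prior = np.full(n, PHI_MIN)
    if usable.any():
        global_mean = float(np.clip(raw[usable].mean(), PHI_MIN, 0.5))
        k = max(min(trend_bins, usable.sum() // 50), 1)
        if k == 1:
            prior[:] = global_mean
        else:
            edges = np.quantile(level[usable], np.linspace(0, 1, k + 1)[1:-1])
            bin_of = np.searchsorted(edges, level, side="right")
            for b in np.unique(bin_of):
                sel = (bin_of == b) & usable
                prior[bin_of == b] = (
                    float(np.clip(raw[sel].mean(), PHI_MIN, 0.5)) if sel.any() else global_mean
                )
    shrunk = (df_tot * np.clip(raw, 0.0, PHI_MAX) + prior_weight * prior) / (
        df_tot + prior_weight
    )
    return np.clip(shrunk, PHI_MIN, PHI_MAX)


def wald_test(meth1, total1, meth2, total2, phi) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wald test of the group methylation difference under beta-binomial variance.

    Returns ``(diff, wald, p)`` where ``diff = 100 * (p1 - p2)`` uses the
    coverage-weighted group proportions and the variance is evaluated at the
    pooled null proportion: ``var_g = p0 (1 - p0) sum n_j (1 + (n_j - 1) phi)
    / (sum n_j)^2``.  Sites with zero null variance get ``wald = 0, p = 1``.
    """
    phat1, _, _, tot1, _, _ = _group_moments(meth1, total1)
    phat2, _, _, tot2, _, _ = _group_moments(meth2, total2)
    x_all = meth1.sum(axis=1) + meth2.sum(axis=1)
    n_all = total1.sum(axis=1) + total2.sum(axis=1)
    p0 = np.where(n_all > 0, x_all / np.maximum(n_all, 1), np.nan)
    pq0 = p0 * (1 - p0)

    def group_var(total, tot):
        w = (total * (1 + (total - 1) * phi[:, None])).sum(axis=1)
        return pq0 * w / np.maximum(tot, 1) ** 2

    var = group_var(total1, tot1) + group_var(total2, tot2)
    diff = 100.0 * (phat1 - phat2)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(var > 0, (phat1 - phat2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = np.where(var > 0, 2.0 * sps.norm.sf(np.abs(wald)), 1.0)
    return diff, wald, p


# ------------------------------------------------------------------------ FDR


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Storey's null-fraction estimate at a single lambda, clipped to [0.05, 1]."""
    n = len(p)
    if n == 0:
        return 1.0
    pi0 = (p > lam).sum() / ((1 - lam) * n)
    return float(np.clip(pi0, 0.05, 1.0))


def ihw_adjust(
    p,
    covariate,
    n_bins: int = 10,
    alpha: float = 0.05,
    min_bin_size: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate-weighted Benjamini-Hochberg adjustment.

    The covariate is cut into ``n_bins`` quantile bins (bins with fewer than
    ``min_bin_size`` hypotheses are merged with their neighbour); each bin's
    weight is proportional to its estimated non-null fraction ``1 - pi0``,
    normalised so the mean weight over all hypotheses is 1; adjusted p-values
    are BH applied to ``p / weight`` (a zero weight maps to adjusted p = 1).
    With a single bin this is exactly BH.  Returns ``(weights, p_adj)``.
    """
    p = np.asarray(p, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if p.shape != covariate.shape:
        raise ValueError("p and covariate must have the same length")
    if not np.isfinite(covariate).all():
        raise ValueError("covariate must be finite for every tested site")
    n = len(p)
    if n == 0:
        return np.array([]), np.array([])

    # quantile binning with small-bin merging
    if n_bins == 1 or n < 2 * min_bin_size:
        bin_of = np.zeros(n, dtype=int)
        k = 1
    else:
        edges = np.quantile(covariate, np.linspace(0, 1, n_bins + 1)[1:-1])
        bin_of = np.searchsorted(edges, covariate, side="right")
        # merge adjacent bins until every bin holds >= min_bin_size hypotheses
        while True:
            ids = np.unique(bin_of)
            counts = {b: int((bin_of == b).sum()) for b in ids}
            small = [b for b in ids if counts[b] < min_bin_size]
            if not small or len(ids) == 1:
                break
            b = small[0]
            ids_list = list(ids)
            i = ids_list.index(b)
            neighbour = ids_list[i - 1] if i > 0 else ids_list[i + 1]
            bin_of[bin_of == b] = neighbour
        ids = np.unique(bin_of)
        remap = {b: i for i, b in enumerate(ids)}
        bin_of = np.vectorize(remap.get)(bin_of)
        k = len(ids)

    signal = np.empty(k)
    for b in range(k):
        signal[b] = 1.0 - storey_pi0(p[bin_of == b])
    mean_signal = signal[bin_of].mean()
    if mean_signal <= 0:
        weights = np.ones(n)
    else:
        weights = signal[bin_of] / mean_signal
    # guard: budget normalisation must hold exactly
    weights = weights / weights.mean()

    with np.errstate(divide="ignore"):
        p_weighted = np.where(weights > 0, np.minimum(p / np.where(weights > 0, weights, 1.0), 1.0), 1.0)
    p_adj = _bh(p_weighted)
    p_adj[weights <= 0] = 1.0
    return weights, p_adj


# ----------------------------------------------------------------- DMCs, DMRs


def call_dmcs(tests: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Threshold site tests into DMCs: ``n1, n2 >= min_samples_per_group``,
    ``p_adj < alpha_adj`` (strict) and ``|diff| >= min_diff`` (inclusive)."""
    ok = (
        (tests["n1"] >= spec.min_samples_per_group)
        & (tests["n2"] >= spec.min_samples_per_group)
        & (tests["p_adj"] < spec.alpha_adj)
        & (tests["diff"].abs() >= spec.min_diff)
    )
    dmcs = tests[ok].copy()
    dmcs["direction"] = np.where(dmcs["diff"] > 0, "hyper_in_group1", "hypo_in_group1")
    # every emitted DMC satisfies all three thresholds (run-time assertion)
    assert (dmcs["p_adj"] < spec.alpha_adj).all()
    assert (dmcs["diff"].abs() >= spec.min_diff).all()
    assert ((dmcs["n1"] >= spec.min_samples_per_group) & (dmcs["n2"] >= spec.min_samples_per_group)).all()
    return dmcs.reset_index(drop=True)


def call_dmrs(dmcs: pd.DataFrame, min_dmcs: int = 3, max_gap: int = 100) -> pd.DataFrame:
    """Greedy chaining of DMCs into DMRs.

    Consecutive same-chromosome DMCs at most ``max_gap`` bp apart (inclusive,
    position-to-position) are joined; maximal chains with at least ``min_dmcs``
    members become DMRs.  Returns one row per DMR with first/last member
    positions, member count, mean difference and majority direction.
    """
    if dmcs.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_dmcs", "mean_diff", "direction", "member_pos"]
        )
    d = dmcs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    chrom = d["chrom"].to_numpy()
    pos = d["pos"].to_numpy()
    new_chain = np.ones(len(d), dtype=bool)
    same = (chrom[1:] == chrom[:-1]) & ((pos[1:] - pos[:-1]) <= max_gap)
    new_chain[1:] = ~same
    chain_id = np.cumsum(new_chain) - 1
    rows = []
    for cid in np.unique(chain_id):
        members = d[chain_id == cid]
        if len(members) < min_dmcs:
            continue
        n_hyper = int((members["diff"] > 0).sum())
        rows.append(
            {
                "chrom": members["chrom"].iloc[0],
                "start": int(members["pos"].min()),
                "end": int(members["pos"].max()),
                "n_dmcs": len(members),
                "mean_diff": float(members["diff"].mean()),
                "direction": "hyper_in_group1" if n_hyper * 2 >= len(members) else "hypo_in_group1",
                "member_pos": list(map(int, members["pos"])),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_dmcs", "mean_diff", "direction", "member_pos"]
    )


def compare_dmc_sets(dmcs_a: pd.DataFrame, dmcs_b: pd.DataFrame) -> dict:
    """Set arithmetic of two DMC sets keyed by (chrom, pos): sizes, intersection,
    union (inclusion-exclusion), shared percentage of the union, and the
    percentage hypermethylated in group1 within each set."""
    keys_a = set(zip(dmcs_a["chrom"], dmcs_a["pos"])) if len(dmcs_a) else set()
    keys_b = set(zip(dmcs_b["chrom"], dmcs_b["pos"])) if len(dmcs_b) else set()
    inter = len(keys_a & keys_b)
    union = len(keys_a) + len(keys_b) - inter

    def pct_hyper(d):
        if len(d) == 0:
            return float("nan")
        return 100.0 * (d["direction"] == "hyper_in_group1").sum() / len(d)

    return {
        "size_a": len(keys_a),
        "size_b": len(keys_b),
        "intersection": inter,
        "union": union,
        "shared_pct": 100.0 * inter / union if union else float("nan"),
        "pct_hyper_group1_a": pct_hyper(dmcs_a),
        "pct_hyper_group1_b": pct_hyper(dmcs_b),
    }


def volcano_table(tests: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Per-site export for volcano plots: diff (group1 - group2), -log10 raw p
    and a pass flag with the first failed-threshold reason."""
    out = tests[["chrom", "pos", "diff", "p"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(np.maximum(tests["p"], 1e-300))
    reasons = []
    for _, r in tests.iterrows():
        if r["n1"] < spec.min_samples_per_group or r["n2"] < spec.min_samples_per_group:
            reasons.append("coverage")
        elif abs(r["diff"]) < spec.min_diff:
            reasons.append("diff")
        elif r["p_adj"] >= spec.alpha_adj:
            reasons.append("p_adj")
        else:
            reasons.append("")
    out["fail_reason"] = reasons
    out["is_dmc"] = out["fail_reason"] == ""
    return out


# ----------------------------------------------------------- model / results


class DifferentialMethylation:
    """Two-group differential methylation model on a :class:`CountMatrix`.

    Parameters
    ----------
    counts : CountMatrix (typically CpG10-filtered).
    spec : ComparisonSpec naming the two group labels (e.g. ``HM15`` vs
        ``MM15``) and the DMC thresholds.  ``diff`` is oriented
        ``group1 - group2``.
    """

    def __init__(self, counts: CountMatrix, spec: ComparisonSpec):
        self.counts = counts
        self.spec = spec
        idx1 = counts.group_indices(spec.group1)
        idx2 = counts.group_indices(spec.group2)
        if len(idx1) == 0 or len(idx2) == 0:
            raise ValueError(
                f"no samples for comparison {spec.group1} vs {spec.group2}"
            )
        self._idx1, self._idx2 = idx1, idx2

    @classmethod
    def from_count_matrix(cls, counts, group1, group2, **kwargs):
        return cls(counts, ComparisonSpec(group1=group1, group2=group2, **kwargs))

    def fit(self, prior_weight: float = 8.0, trend_bins: int = 4) -> "DifferentialResults":
        """Estimate shrunk dispersions, run the Wald test at every eligible site
        (>= min_samples_per_group covered bulls in each group), apply the
        covariate-weighted FDR adjustment, and return the results object."""
        cm = self.counts
        meth1, total1 = cm.meth[:, self._idx1], cm.total[:, self._idx1]
        meth2, total2 = cm.meth[:, self._idx2], cm.total[:, self._idx2]
        n1 = (total1 > 0).sum(axis=1)
        n2 = (total2 > 0).sum(axis=1)
        eligible = (n1 >= self.spec.min_samples_per_group) & (
            n2 >= self.spec.min_samples_per_group
        )
        e = np.flatnonzero(eligible)
        m1, t1 = meth1[e], total1[e]
        m2, t2 = meth2[e], total2[e]
        phi = estimate_dispersion_shrunk(
            m1, t1, m2, t2, prior_weight=prior_weight, trend_bins=trend_bins
        )
        diff, wald, p = wald_test(m1, t1, m2, t2, phi)
        phat1 = m1.sum(axis=1) / np.maximum(t1.sum(axis=1), 1)
        phat2 = m2.sum(axis=1) / np.maximum(t2.sum(axis=1), 1)
        covariate = 100.0 * (m1.sum(axis=1) + m2.sum(axis=1)) / np.maximum(
            t1.sum(axis=1) + t2.sum(axis=1), 1
        )
        weights, p_adj = ihw_adjust(
            p, covariate, n_bins=self.spec.ihw_bins, alpha=self.spec.ihw_alpha
        )
        tests = pd.DataFrame(
            {
                "chrom": cm.sites["chrom"].to_numpy()[e],
                "pos": cm.sites["pos"].to_numpy()[e],
                "n1": n1[e],
                "n2": n2[e],
                "mean1": 100.0 * phat1,
                "mean2": 100.0 * phat2,
                "diff": diff,
                "phi": phi,
                "wald": wald,
                "p": p,
                "weight": weights,
                "p_adj": p_adj,
            }
        )
        return DifferentialResults(self, tests, n_eligible=len(e), n_total=cm.n_sites)


@dataclass
class DifferentialResults:
    """Fitted per-site tests plus thresholded DMC/DMR derivations."""

    model: DifferentialMethylation
    tests: pd.DataFrame
    n_eligible: int
    n_total: int
    _dmcs: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def spec(self) -> ComparisonSpec:
        return self.model.spec

    @property
    def dmcs(self) -> pd.DataFrame:
        if self._dmcs is None:
            self._dmcs = call_dmcs(self.tests, self.spec)
        return self._dmcs

    def dmrs(self, min_dmcs: int = 3, max_gap: int = 100) -> pd.DataFrame:
        return call_dmrs(self.dmcs, min_dmcs=min_dmcs, max_gap=max_gap)

    def volcano_table(self) -> pd.DataFrame:
        return volcano_table(self.tests, self.spec)

    def plot_volcano(self, ax=None):
        """Volcano plot: methylation difference vs -log10 raw p, DMCs in red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        vt = self.volcano_table()
        ax.scatter(vt["diff"], vt["neg_log10_p"], s=4, c="grey", alpha=0.4, linewidths=0)
        hit = vt[vt["is_dmc"]]
        ax.scatter(hit["diff"], hit["neg_log10_p"], s=6, c="red", linewidths=0)
        ax.axvline(self.spec.min_diff, ls="--", c="k", lw=0.6)
        ax.axvline(-self.spec.min_diff, ls="--", c="k", lw=0.6)
        ax.set_xlabel(f"methylation difference ({self.spec.group1} - {self.spec.group2}, points)")
        ax.set_ylabel("-log10 raw p")
        return ax

    def summary(self) -> str:
        s = self.spec
        dmrs = self.dmrs()
        lines = [
            "Differential methylation results",
            "================================",
            f"comparison:        {s.group1} vs {s.group2} (diff = {s.group1} - {s.group2})",
            f"sites total:       {self.n_total}",
            f"sites eligible:    {self.n_eligible} (>= {s.min_samples_per_group} bulls/group)",
            f"DMCs:              {len(self.dmcs)} (p_adj < {s.alpha_adj}, |diff| >= {s.min_diff})",
            f"  hyper in {s.group1}: "
            f"{(self.dmcs['direction'] == 'hyper_in_group1').sum()}"
            + (
                f" ({100.0 * (self.dmcs['direction'] == 'hyper_in_group1').mean():.1f}%)"
                if len(self.dmcs)
                else ""
            ),
            f"DMRs:              {len(dmrs)} (>= 3 DMCs, gaps <= 100 bp)",
            f"median shrunk phi: {np.median(self.tests['phi']):.4f}" if len(self.tests) else "",
        ]
        return "\n".join(x for x in lines if x)

    def to_csv(self, dmc_path=None, dmr_bed_path=None, dmr_csv_path=None):
        """Write the DMC table (1-based positions), DMR BED (0-based half-open)
        and DMR companion CSV."""
        if dmc_path is not None:
            out = self.dmcs.copy()
            out["pos"] = out["pos"] + 1
            out.to_csv(dmc_path, index=False)
        dmrs = self.dmrs()
        if dmr_bed_path is not None:
            bed = dmrs.copy()
            if len(bed):
                bed["end"] = bed["end"] + 2  # cover the final CpG dyad
            bed[["chrom", "start", "end"]].to_csv(
                dmr_bed_path, sep="\t", header=False, index=False
            )
        if dmr_csv_path is not None:
            out = dmrs.copy()
            out["member_pos"] = out["member_pos"].apply(
                lambda xs: ";".join(str(x + 1) for x in xs)
            )
            out.to_csv(dmr_csv_path, index=False)
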