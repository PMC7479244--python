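"""Count matrices, the CpG10 coverage filter, QC summaries and permutation tests.

The central object is :class:`CountMatrix`: per-CpG, per-sample (methylated,
total) read counts.  A cell with ``total == 0`` is *missing* — a site not
covered in that sample.  Methylation percentages are always derived from the
counts as ``100 * count_m / count_total`` and are undefined (NaN) for missing
cells, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io

HYPER_THRESHOLD = 80.0  # methylation % strictly above -> hypermethylated
HYPO_THRESHOLD = 20.0  # methylation % strictly below -> hypomethylated


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced semen sample: a bull at a given age under a diet group."""

    sample_id: str
    bull_id: str
    group: str  # "HM" or "MM"
    age: int  # months

    def __post_init__(self):
        if self.group not in ("HM", "MM"):
            raise ValueError(f"unknown diet group {self.group!r}")

    @property
    def group_label(self) -> str:
        return f"{self.group}{self.age}"


def samples_from_sheet(sheet: pd.DataFrame) -> list[SampleRecord]:
    return [
        SampleRecord(r.sample_id, r.bull_id, r.group, int(r.age))
        for r in sheet.itertuples(index=False)
    ]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a Monte-Carlo permutation test (add-one p-value estimator)."""

    statistic: float
    n_perm: int
    p_value: float
    seed: int | None = None


class CountMatrix:
    """Sites x samples matrix of (methylated, total) bisulfite read counts.

    Parameters
    ----------
    sites : DataFrame with columns ``chrom`` and ``pos`` (0-based forward-strand
        cytosine of the CpG dyad), unique and sorted.
    samples : list of :class:`SampleRecord` in column order.
    meth, total : integer arrays of shape (n_sites, n_samples); ``total == 0``
        marks a missing cell.
    """

    def __init__(self, sites: pd.DataFrame, samples: list[SampleRecord], meth, total):
        meth = np.asarray(meth, dtype=np.int64)
        total = np.asarray(total, dtype=np.int64)
        if meth.shape != total.shape or meth.shape != (len(sites), len(samples)):
            raise ValueError("count array shapes inconsistent with sites/samples")
        if (meth < 0).any() or (total < 0).any():
            raise ValueError("negative read counts")
        if (meth > total).any():
            raise ValueError("count_methylated exceeds count_total")
        sites = sites.reset_index(drop=True)
        if sites.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) sites")
        self.sites = sites[["chrom", "pos"]]
        self.samples = list(samples)
        self.meth = meth
        self.total = total

    # ------------------------------------------------------------------ basic
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def group_indices(self, group_label: str) -> np.ndarray:
        """Column indices of samples whose group_label (e.g. 'HM15') matches."""
        return np.array(
            [i for i, s in enumerate(self.samples) if s.group_label == group_label],
            dtype=int,
        )

    @classmethod
    def from_records(
        cls, per_sample: dict[str, pd.DataFrame], samples: list[SampleRecord]
    ) -> "CountMatrix":
        """Assemble from per-sample ``chrom,pos,count_m,count_u`` record frames."""
        ids = [s.sample_id for s in samples]
        missing = [i for i in ids if i not in per_sample]
        if missing:
            raise ValueError(f"no records for samples {missing}")
        frames = []
        for sid in ids:
            df = per_sample[sid]
            f = df[["chrom", "pos"]].copy()
            f["m_" + sid] = df["count_m"].to_numpy()
            f["t_" + sid] = (df["count_m"] + df["count_u"]).to_numpy()
            frames.append(f.set_index(["chrom", "pos"]))
        wide = pd.concat(frames, axis=1, join="outer").sort_index()
        meth = wide[[f"m_{sid}" for sid in ids]].fillna(0).to_numpy(dtype=np.int64)
        total = wide[[f"t_{sid}" for sid in ids]].fillna(0).to_numpy(dtype=np.int64)
        sites = wide.index.to_frame(index=False)
        return cls(sites, samples, meth, total)

    @classmethod
    def from_coverage_dir(
        cls, directory, sheet: pd.DataFrame, merge_strands: bool = True
    ) -> "CountMatrix":
        """Read ``<sample_id>.cov`` files for every sheet row, optionally merging
        CpG-dyad strand records (see :func:`merge_strand_counts`)."""
        from pathlib import Path

        per_sample = {}
        for sid in sheet["sample_id"]:
            df = _io.read_coverage_file(Path(directory) / f"{sid}.cov", sid)
            if merge_strands:
                df = merge_strand_counts(df, mode="merged")
            per_sample[sid] = df
        return cls.from_records(per_sample, samples_from_sheet(sheet))

    # ------------------------------------------------------------ derivations
    def methylation_percent(self) -> pd.DataFrame:
        """Sites x samples methylation percentages; NaN where missing."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(self.total > 0, 100.0 * self.meth / np.maximum(self.total, 1), np.nan)
        return pd.DataFrame(pct, columns=self.sample_ids).set_index(
            pd.MultiIndex.from_frame(self.sites)
        )

    def filter_cpg10(self, min_reads: int = 10) -> "CountMatrix":
        """Apply the coverage filter: cells with fewer than ``min_reads`` total
        reads become missing; sites missing everywhere are dropped.  Idempotent."""
        if min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        keep_cell = self.total >= min_reads
        meth = np.where(keep_cell, self.meth, 0)
        total = np.where(keep_cell, self.total, 0)
        keep_site = total.sum(axis=1) > 0
        return CountMatrix(
            self.sites.loc[keep_site], self.samples, meth[keep_site], total[keep_site]
        )

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountMatrix(
            self.sites, [self.samples[i] for i in idx], self.meth[:, idx], self.total[:, idx]
        )

    def to_wide_csv(self, path) -> None:
        """Write the methylation-percentage matrix (1-based positions) as CSV."""
        pct = self.methylation_percent().reset_index()
        pct["pos"] = pct["pos"] + 1
        pct.to_csv(path, index=False)


def filter_cpg10(matrix: CountMatrix, min_reads: int = 10) -> CountMatrix:
    """Functional form of :meth:`CountMatrix.filter_cpg10` (CpG10 rule: keep
    cells covered by at least ``min_reads`` uniquely mapped reads)."""
    return matrix.filter_cpg10(min_reads)


def merge_strand_counts(records: pd.DataFrame, mode: str = "merged") -> pd.DataFrame:
    """Collapse CpG-dyad strand records onto the forward-strand cytosine.

    A CpG dyad yields a forward-strand call at position ``p`` and a
    reverse-strand call at ``p + 1``.  In ``merged`` mode adjacent records are
    paired greedily left-to-right within a chromosome (a record at ``p + 1``
    merges into a not-yet-paired record at ``p``) and their counts summed under
    key ``p``.  ``forward_only`` leaves records untouched.  The dialect carries
    no strand column, so a dyad covered only on the reverse strand cannot be
    re-keyed and is kept as-is.
    """
    if mode == "forward_only":
        return records.copy()
    if mode != "merged":
        raise ValueError(f"unknown merge mode {mode!r}")
    if records.empty:
        return records.copy()
    df = records.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    owner = np.arange(len(df))
    prev_unpaired = -1
    for i in range(len(df)):
        if (
            prev_unpaired >= 0
            and chrom[i] == chrom[prev_unpaired]
            and pos[i] == pos[prev_unpaired] + 1
        ):
            owner[i] = prev_unpaired
            prev_unpaired = -1
        else:
            prev_unpaired = i
    out = (
        df.assign(_owner=owner)
        .groupby("_owner", sort=True)
        .agg(
            chrom=("chrom", "first"),
            pos=("pos", "first"),
            count_m=("count_m", "sum"),
            count_u=("count_u", "sum"),
        )
        .reset_index(drop=True)
    )
    return out


def methylation_percent(count_m: int, count_total: int) -> float:
    """Per-site methylation percentage, 100 * C / (C + T) reads."""
    if count_total < 1:
        raise ValueError("methylation percentage undefined for zero coverage")
    if count_m < 0 or count_m > count_total:
        raise ValueError("invalid counts")
    return 100.0 * count_m / count_total


def classify_sites(percentages) -> pd.Series:
    """Label methylation percentages hypo (<20), intermediate ([20, 80], both
    boundaries inclusive) or hyper (>80)."""
    arr = np.asarray(percentages, dtype=float)
    finite = arr[~np.isnan(arr)]
    if ((finite < 0) | (finite > 100)).any():
        raise ValueError("methylation percentages must lie in [0, 100]")
    labels = np.where(
        np.isnan(arr),
        None,
        np.where(arr < HYPO_THRESHOLD, "hypo", np.where(arr > HYPER_THRESHOLD, "hyper", "intermediate")),
    )
    return pd.Series(labels, dtype="object")


def class_fractions(percentages) -> dict[str, float]:
    """Percentage of non-missing sites in each methylation class (sums to 100)."""
    labels = classify_sites(percentages)
    labels = labels.dropna()
    n = len(labels)
    if n == 0:
        return {"hyper": np.nan, "intermediate": np.nan, "hypo": np.nan}
    counts = labels.value_counts()
    return {
        cls: 100.0 * counts.get(cls, 0) / n for cls in ("hyper", "intermediate", "hypo")
    }


def estimate_conversion_rate(spikein_converted: int, spikein_total: int) -> float:
    """Bisulfite conversion rate (%) from the unmethylated spike-in control."""
    if spikein_total < 1:
        import warnings

        warnings.warn("spike-in total is zero; conversion rate missing", stacklevel=2)
        return float("nan")
    return 100.0 * spikein_converted / spikein_total


def qc_summary(
    matrix: CountMatrix, spikeins: pd.DataFrame | None = None, min_reads: int = 10
) -> pd.DataFrame:
    """Per-sample QC table: covered CpGs, mean coverage, % CpGs10, conversion
    rate, mean methylation at CpGs10 and hyper/intermediate/hypo fractions."""
    rows = []
    conv = {}
    if spikeins is not None:
        for r in spikeins.itertuples(index=False):
            conv[r.sample_id] = estimate_conversion_rate(r.converted, r.total)
    for j, s in enumerate(matrix.samples):
        total = matrix.total[:, j]
        covered = total > 0
        n_cov = int(covered.sum())
        cpg10 = total >= min_reads
        pct = np.full(matrix.n_sites, np.nan)
        pct[cpg10] = 100.0 * matrix.meth[cpg10, j] / total[cpg10]
        fr = class_fractions(pct)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group_label": s.group_label,
                "n_covered_cpgs": n_cov,
                "mean_coverage": float(total[covered].mean()) if n_cov else np.nan,
                "pct_cpg10": 100.0 * cpg10.sum() / n_cov if n_cov else np.nan,
                "conversion_rate_pct": conv.get(s.sample_id, np.nan),
                "mean_methylation_cpg10_pct": float(np.nanmean(pct)) if cpg10.any() else np.nan,
                "pct_hyper": fr["hyper"],
                "pct_intermediate": fr["intermediate"],
                "pct_hypo": fr["hypo"],
            }
        )
    return pd.DataFrame(rows)


def _between_group_variance(values: np.ndarray, group_slices: list[np.ndarray]) -> float:
    means = np.array([values[idx].mean() for idx in group_slices])
    return float(means.var())


def ksample_permutation_test(
    groups: list, n_perm: int = 100_000, seed: int | None = None, statistic=None
) -> PermutationResult:
    """k-sample Monte-Carlo permutation test.

    ``groups`` is a list of 1-d value arrays (one per group).  The default
    statistic is the variance of the group means (any location-sensitive
    statistic may be passed as ``statistic(values, group_slices)``).  Labels are
    permuted uniformly over all observations; the p-value uses the add-one
    estimator ``(1 + #{perm stat >= observed}) / (n_perm + 1)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group")
    values = np.concatenate(groups)
    if len(values) < 2:
        raise ValueError("need at least two observations")
    bounds = np.cumsum([0] + sizes)
    slices = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(sizes))]
    stat_fn = statistic or _between_group_variance
    observed = stat_fn(values, slices)

    rng = np.random.default_rng(seed)
    count_ge = 0
    chunk = 2000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # permute values (equivalent to permuting labels uniformly)
        order = np.argsort(rng.random((m, len(values))), axis=1)
        perm_vals = values[order]
        if statistic is None:  # vectorised default: variance of group means
            means = np.stack([perm_vals[:, idx].mean(axis=1) for idx in slices], axis=1)
            stats = means.var(axis=1)
        else:
            stats = np.empty(m)
            for r in range(m):
                stats[r] = stat_fn(perm_vals[r], slices)
        count_ge += int((stats >= observed - 1e-15).sum())
        done += m
    p = (1 + count_ge) / (n_perm + 1)
    return PermutationResult(statistic=float(observed), n_perm=n_perm, p_value=p, seed=seed)
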