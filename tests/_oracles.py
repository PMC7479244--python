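"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives the expected answer by exhaustive enumeration or
per-base labelling, deliberately avoiding the interval-tree / vectorised code
paths of the package.
"""

from itertools import combinations

import numpy as np

# label codes for the per-base gene-feature oracle, in precedence order
FEATURE_CODES = [
    "TSS",
    "TTS",
    "5'UTR",
    "3'UTR",
    "exon",
    "intron",
    "promoter",
    "upstream_10kb",
    "downstream_10kb",
    "intergenic",
]


def paint_gene_features(genes, chrom_len):
    """Per-base gene-feature labels: paint windows in reverse precedence so the
    highest-precedence feature ends up on top.  Window arithmetic is written
    out directly from the definitions (TSS/TTS +/-100, promoter -2000..-100,
    10-kb flanks), independent of the package's derivation code."""
    arr = np.full(chrom_len, FEATURE_CODES.index("intergenic"), dtype=np.int8)

    def paint(code, s, e):
        s, e = max(0, s), min(chrom_len, e)
        if e > s:
            arr[s:e] = FEATURE_CODES.index(code)

    for pass_code in reversed(FEATURE_CODES[:-1]):
        for g in genes:
            t = g.start if g.strand == "+" else g.end - 1  # first transcribed base
            u = g.end - 1 if g.strand == "+" else g.start
            if pass_code == "TSS":
                paint("TSS", t - 100, t + 101)
            elif pass_code == "TTS":
                paint("TTS", u - 100, u + 101)
            elif pass_code == "5'UTR":
                for s, e in g.utr5:
                    paint("5'UTR", s, e)
            elif pass_code == "3'UTR":
                for s, e in g.utr3:
                    paint("3'UTR", s, e)
            elif pass_code == "exon":
                for s, e in g.exons:
                    paint("exon", s, e)
            elif pass_code == "intron":
                # gene body not covered by an exon
                body = np.zeros(chrom_len, dtype=bool)
                body[max(0, g.start) : min(chrom_len, g.end)] = True
                for s, e in g.exons:
                    body[max(0, s) : min(chrom_len, e)] = False
                arr[body] = FEATURE_CODES.index("intron")
            elif pass_code == "promoter":
                if g.strand == "+":
                    paint("promoter", t - 2000, t - 100)
                else:
                    paint("promoter", t + 101, t + 2001)
            elif pass_code == "upstream_10kb":
                if g.strand == "+":
                    paint("upstream_10kb", t - 10_000, t)
                else:
                    paint("upstream_10kb", t + 1, t + 10_001)
            elif pass_code == "downstream_10kb":
                if g.strand == "+":
                    paint("downstream_10kb", u + 1, u + 10_001)
                else:
                    paint("downstream_10kb", u - 10_000, u)
    return arr


def paint_cpg_context(islands, chrom_len):
    """Per-base island/shore/shelf/open_sea labels from raw island intervals:
    shelf = within 4000 bp of an island, overwritten by shore (within 2000),
    overwritten by island itself."""
    ctx = np.full(chrom_len, 3, dtype=np.int8)  # open_sea
    for pad, code in ((4000, 2), (2000, 1), (0, 0)):
        for s, e in islands:
            a, b = max(0, s - pad), min(chrom_len, e + pad)
            ctx[a:b] = code
    return ctx


def context_label_for_region(ctx_array, start, end, min_overlap=0.75):
    """Apply the 75% rule from the per-base labels."""
    length = end - start
    counts = np.bincount(ctx_array[start:end], minlength=4)
    for code, name in ((0, "island"), (1, "shore"), (2, "shelf")):
        if counts[code] / length >= min_overlap:
            return name
    return "open_sea"


def paint_repeats(repeats_df, chrom, chrom_len):
    masks = {}
    for cls in repeats_df["name"].unique():
        m = np.zeros(chrom_len, dtype=bool)
        sub = repeats_df[(repeats_df["name"] == cls) & (repeats_df["chrom"] == chrom)]
        for s, e in sub[["start", "end"]].itertuples(index=False):
            m[max(0, s) : min(chrom_len, e)] = True
        masks[cls] = m
    return masks


def brute_force_dmrs(positions, min_dmcs=3, max_gap=100):
    """All maximal windows of sorted positions with consecutive gaps <= max_gap
    and at least min_dmcs members, found by testing every candidate window."""
    pos = sorted(positions)
    n = len(pos)
    out = []
    for i in range(n):
        for j in range(i + min_dmcs - 1, n):
            window = pos[i : j + 1]
            if any(b - a > max_gap for a, b in zip(window, window[1:])):
                continue
            left_ok = i == 0 or pos[i] - pos[i - 1] > max_gap
            right_ok = j == n - 1 or pos[j + 1] - pos[j] > max_gap
            if left_ok and right_ok:
                out.append((pos[i], pos[j], j - i + 1))
    return out


def exhaustive_two_sample_one_sided(values, n1, statistic):
    """Exact one-sided permutation p over all C(n, n1) group-1 choices:
    P(stat >= observed), observed = statistic on the first n1 values."""
    values = np.asarray(values, dtype=float)
    idx = range(len(values))
    observed = statistic(values, np.arange(n1))
    count = total = 0
    for c in combinations(idx, n1):
        stat = statistic(values, np.array(c))
        total += 1
        if stat >= observed - 1e-12:
            count += 1
    return count / total


def exhaustive_stratified_two_sided(values, mask1, strata):
    """Exact stratified two-sided p (doubling the smaller tail, capped at 1)
    over the product of within-stratum label arrangements."""
    values = np.asarray(values, dtype=float)
    mask1 = np.asarray(mask1, dtype=bool)
    strata = np.asarray(strata)

    def mean_diff(m):
        return values[m].mean() - values[~m].mean()

    observed = mean_diff(mask1)
    per_stratum = []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        k = int(mask1[idx].sum())
        per_stratum.append([set(c) for c in combinations(idx.tolist(), k)])

    def walk(i, chosen):
        if i == len(per_stratum):
            yield chosen
            return
        for c in per_stratum[i]:
            yield from walk(i + 1, chosen | c)

    stats = []
    for chosen in walk(0, set()):
        m = np.zeros(len(values), dtype=bool)
        m[list(chosen)] = True
        stats.append(mean_diff(m))
    stats = np.array(stats)
    total = len(stats)
    p_ge = (stats >= observed - 1e-12).sum() / total
    p_le = (stats <= observed + 1e-12).sum() / total
    return min(1.0, 2.0 * min(p_ge, p_le)), total
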