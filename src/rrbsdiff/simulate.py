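"""Synthetic RRBS cohort generator.

Builds a toy genome with annotation tracks (genes, CpG islands, repeats),
performs an in-silico MspI reduced-representation digest with size selection,
and simulates per-sample bisulfite count data with planted diet effects — in
the same text formats the analysis pipeline consumes.

The default parameters encode the global structure of mature bull sperm RRBS
data: ~50% mean methylation with a strongly bimodal per-CpG distribution
(~47% of sites above 80%, ~46% below 20%, ~7% intermediate), ~25x coverage at
retained sites, a bisulfite conversion rate of 99.4%, a small planted fraction
of differential CpGs biased toward hypermethylation in the HM group, and
bull-level variability that dominates the diet effect.  Samples exist for
three cohorts: HM15 (high-then-moderate diet, 15 months), MM15 and MM16
(moderate diet, 15 and 16 months); MM15 and MM16 share the same underlying
methylome truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as _io
from .core import CountMatrix, SampleRecord, samples_from_sheet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _T = 67, 71, 84


@dataclass
class MixtureSpec:
    """Three-component beta mixture for baseline per-CpG methylation levels."""

    proportions: tuple[float, float, float] = (0.471, 0.458, 0.071)  # hyper, hypo, mid
    # components are sharply bimodal (means ~0.98 / ~0.02) so that the
    # *observed* class split at ~25x coverage matches the ~47/46/7 structure
    hyper_beta: tuple[float, float] = (60.0, 1.5)
    hypo_beta: tuple[float, float] = (1.5, 60.0)
    intermediate_beta: tuple[float, float] = (5.0, 5.0)


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 2_500_000
    gc_content: float = 0.5
    cg_depletion: float = 0.5  # P(background CpG dinucleotide mutated C->T)
    n_genes: int = 150
    n_cgis: int = 200
    repeat_fraction: dict = field(
        default_factory=lambda: {
            "LINE": 0.12,
            "SINE": 0.08,
            "LTR": 0.04,
            "satellite": 0.02,
            "simple": 0.02,
        }
    )
    # digest / size selection (genomic fragment length, adapters excluded)
    frag_min: int = 40
    frag_max: int = 290
    # coverage model
    mean_coverage: float = 25.0
    coverage_dispersion: float = 8.0  # negative-binomial size parameter
    # methylation model
    baseline_mixture: MixtureSpec = field(default_factory=MixtureSpec)
    planted_dmc_fraction: float = 0.01
    planted_block_fraction: float = 0.3  # share of planted sites laid in CpG blocks
    effect_size: float = 15.0  # percentage points
    hyper_bias: float = 0.7  # P(planted effect raises HM methylation)
    biological_dispersion: float = 0.02  # beta-binomial phi
    bull_jitter_sd: float = 0.6  # logit-scale bull random effect
    conversion_rate: float = 0.994
    n_age_dmcs: int = 0  # optional planted 15-vs-16-month effects
    # cohort
    n_hm15: int = 9
    n_mm15: int = 7
    n_mm16: int = 9
    spikein_cytosines: int = 50_000
    # pyrosequencing assay
    pyro_noise_sd: float = 2.0
    pyro_inconsistent_rate: float = 0.05

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1000:
            raise ValueError("degenerate genome configuration")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if self.frag_min >= self.frag_max:
            raise ValueError("frag_min must be < frag_max")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        p = self.baseline_mixture.proportions
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("baseline mixture proportions must sum to 1")
        for name in (
            "cg_depletion",
            "planted_dmc_fraction",
            "planted_block_fraction",
            "hyper_bias",
            "conversion_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.biological_dispersion < 1.0):
            raise ValueError("biological_dispersion must be in [0, 1)")
        if self.n_genes < 0 or self.n_cgis < 0:
            raise ValueError("n_genes / n_cgis must be non-negative")
        if self.n_genes == 0:
            raise ValueError("degenerate config: zero genes")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "baseline_mixture" in d and isinstance(d["baseline_mixture"], dict):
            m = d["baseline_mixture"]
            d["baseline_mixture"] = MixtureSpec(
                proportions=tuple(m.get("proportions", MixtureSpec().proportions)),
                hyper_beta=tuple(m.get("hyper_beta", MixtureSpec().hyper_beta)),
                hypo_beta=tuple(m.get("hypo_beta", MixtureSpec().hypo_beta)),
                intermediate_beta=tuple(
                    m.get("intermediate_beta", MixtureSpec().intermediate_beta)
                ),
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    gtf_records: list[dict]
    cgis: pd.DataFrame  # chrom, start, end (0-based half-open)
    repeats: pd.DataFrame  # chrom, start, end, name (repeat class)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


# --------------------------------------------------------------------- genome


def _random_sequence(length: int, gc: float, depletion: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=length, p=p)]
    # CpG depletion: mutate a fraction of background CG dinucleotides (C -> T),
    # giving the toy genome a sub-unity observed/expected CpG ratio outside CGIs
    is_cg = (arr[:-1] == _C) & (arr[1:] == _G)
    idx = np.flatnonzero(is_cg)
    if len(idx):
        mutate = idx[rng.random(len(idx)) < depletion]
        arr[mutate] = _T
    return arr


def _cgi_sequence(length: int, rng) -> np.ndarray:
    """CpG-rich subsequence: frequent explicit CG dinucleotides on a GC-rich bed."""
    out = np.empty(length, dtype=np.uint8)
    i = 0
    emit_cg = rng.random(length) < 0.18
    single = _BASES[rng.choice(4, size=length, p=[0.2, 0.3, 0.3, 0.2])]
    for k in range(length):
        if i >= length:
            break
        if emit_cg[k] and i + 1 < length:
            out[i] = _C
            out[i + 1] = _G
            i += 2
        else:
            out[i] = single[k]
            i += 1
    return out[:length]


def _sample_nonoverlapping(n: int, lengths, chrom_len: int, rng, occupied=None):
    """Greedy rejection sampling of non-overlapping intervals."""
    intervals = list(occupied or [])
    out = []
    attempts = 0
    while len(out) < n and attempts < 50 * max(n, 1):
        attempts += 1
        ln = int(lengths(rng))
        if ln >= chrom_len:
            continue
        s = int(rng.integers(0, chrom_len - ln))
        e = s + ln
        if any(s < oe and os_ < e for os_, oe in intervals):
            continue
        intervals.append((s, e))
        out.append((s, e))
    out.sort()
    return out


def generate_toy_genome(config: SimulationConfig, rng=None) -> GenomeBundle:
    """Generate sequences plus gene-model, CGI and repeat tracks.

    CGIs are CpG-enriched rewritten subsequences; genes carry exons, UTRs and
    both strands; repeats are coordinate intervals by class.  Deterministic for
    a given (config, seed).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    sequences: dict[str, str] = {}
    gtf_records: list[dict] = []
    cgi_rows, rep_rows = [], []
    genes_per_chrom = _split_count(config.n_genes, config.n_chroms)
    cgis_per_chrom = _split_count(config.n_cgis, config.n_chroms)

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        arr = _random_sequence(L, config.gc_content, config.cg_depletion, rng)

        cgi_iv = _sample_nonoverlapping(
            cgis_per_chrom[ci], lambda r: r.integers(400, 1201), L, rng
        )
        for s, e in cgi_iv:
            arr[s:e] = _cgi_sequence(e - s, rng)
            cgi_rows.append((chrom, s, e))

        gene_iv = _sample_nonoverlapping(
            genes_per_chrom[ci], lambda r: r.integers(3000, 15001), L, rng
        )
        for gi, (s, e) in enumerate(gene_iv):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{ci + 1:02d}{gi + 1:04d}"
            gtf_records.extend(_gene_records(chrom, s, e, strand, gene_id, rng))

        for cls, frac in config.repeat_fraction.items():
            lo, hi = _REPEAT_LENGTHS[cls]
            target = int(frac * L)
            covered = 0
            while covered < target:
                ln = int(rng.integers(lo, hi + 1))
                s = int(rng.integers(0, max(L - ln, 1)))
                rep_rows.append((chrom, s, s + ln, cls))
                covered += ln

        sequences[chrom] = arr.tobytes().decode("ascii")

    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "name"])
    repeats = repeats.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    return GenomeBundle(sequences, gtf_records, cgis, repeats)


_REPEAT_LENGTHS = {
    "LINE": (500, 3000),
    "SINE": (100, 300),
    "LTR": (300, 1000),
    "satellite": (200, 2000),
    "simple": (20, 100),
}


def _split_count(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


def _gene_records(chrom, start, end, strand, gene_id, rng) -> list[dict]:
    """Exon/intron structure with terminal UTRs; first/last exon at the span ends."""
    n_exons = int(rng.integers(2, 6))
    span = end - start
    # 2*(n_exons-1) internal boundaries, each segment >= 30 bp
    while True:
        cuts = np.sort(rng.integers(30, span - 30, size=2 * (n_exons - 1)))
        seg = np.diff(np.concatenate([[0], cuts, [span]]))
        if (seg >= 30).all():
            break
    bounds = np.concatenate([[0], cuts, [span]]) + start
    exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)]
    tx_id = gene_id + ".t1"
    recs = [
        dict(chrom=chrom, feature="gene", start=start, end=end, strand=strand, gene_id=gene_id),
        dict(
            chrom=chrom,
            feature="transcript",
            start=start,
            end=end,
            strand=strand,
            gene_id=gene_id,
            transcript_id=tx_id,
        ),
    ]
    for s, e in exons:
        recs.append(
            dict(
                chrom=chrom,
                feature="exon",
                start=s,
                end=e,
                strand=strand,
                gene_id=gene_id,
                transcript_id=tx_id,
            )
        )
    first, last = exons[0], exons[-1]
    utr5_len = int(rng.integers(20, max(21, min(200, first[1] - first[0]))))
    utr3_len = int(rng.integers(20, max(21, min(200, last[1] - last[0]))))
    if strand == "+":
        utr5 = (first[0], first[0] + utr5_len)
        utr3 = (last[1] - utr3_len, last[1])
    else:
        utr5 = (last[1] - utr5_len, last[1])
        utr3 = (first[0], first[0] + utr3_len)
    recs.append(
        dict(
            chrom=chrom,
            feature="five_prime_utr",
            start=utr5[0],
            end=utr5[1],
            strand=strand,
            gene_id=gene_id,
            transcript_id=tx_id,
        )
    )
    recs.append(
        dict(
            chrom=chrom,
            feature="three_prime_utr",
            start=utr3[0],
            end=utr3[1],
            strand=strand,
            gene_id=gene_id,
            transcript_id=tx_id,
        )
    )
    return recs


# --------------------------------------------------------------------- digest


def digest_mspi(
    sequence: str, frag_min: int = 40, frag_max: int = 290, internal_only: bool = False
) -> list[tuple[int, int]]:
    """In-silico MspI digest with size selection.

    The enzyme cuts C^CGG — between the first C and CGG of every CCGG
    occurrence.  Fragments are the intervals between consecutive cut positions
    (0-based half-open); only those with ``frag_min <= length <= frag_max`` are
    returned.  With ``internal_only`` the terminal pieces (whose outer end is a
    chromosome end, not a cut site) are excluded, as in a real
    reduced-representation library where both fragment ends must be MspI sites.
    """
    if re.search("[^ACGTN]", sequence):
        raise ValueError("sequence must be uppercase ACGTN")
    cuts = [m.start() + 1 for m in re.finditer("CCGG", sequence)]
    if not cuts:
        return []
    bounds = [0] + cuts + [len(sequence)]
    frags = list(zip(bounds[:-1], bounds[1:]))
    if internal_only:
        frags = frags[1:-1]
    return [(s, e) for s, e in frags if frag_min <= e - s <= frag_max]


def cpg_positions(sequence: str) -> np.ndarray:
    """0-based positions of the forward-strand C of every CpG dyad."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))


def cpg_oe_ratio(sequence: str) -> float:
    """Observed/expected CpG ratio: n(CG) * L / (n(C) * n(G))."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n_c = int((arr == _C).sum())
    n_g = int((arr == _G).sum())
    if n_c == 0 or n_g == 0:
        return float("nan")
    n_cg = int(((arr[:-1] == _C) & (arr[1:] == _G)).sum())
    return n_cg * len(arr) / (n_c * n_g)


# ------------------------------------------------------------------ methylome


def simulate_methylome(
    bundle: GenomeBundle,
    fragments: dict[str, list[tuple[int, int]]],
    config: SimulationConfig,
    rng=None,
) -> pd.DataFrame:
    """Draw per-CpG ground-truth methylation levels for each diet/age group.

    CpGs are restricted to retained fragments.  Baseline levels come from the
    three-component beta mixture; ``planted_dmc_fraction`` of CpGs receive a
    diet effect of exactly ``effect_size`` points in the HM group (direction
    hyper with probability ``hyper_bias``); a share of planted sites is laid in
    blocks of 3-5 consecutive CpGs so region-level signal exists.  MM15 and
    MM16 share identical truth unless ``n_age_dmcs > 0``.

    Returns the SimulationTruth table with columns ``chrom, pos, baseline,
    level_hm, level_mm15, level_mm16, planted_dmc, planted_direction,
    block_id, baseline_adjusted``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows = []
    for chrom in sorted(bundle.sequences):
        frags = fragments.get(chrom, [])
        if not frags:
            continue
        pos = cpg_positions(bundle.sequences[chrom])
        starts = np.array([s for s, _ in frags])
        ends = np.array([e for _, e in frags])
        k = np.searchsorted(starts, pos, side="right") - 1
        inside = (k >= 0) & (pos + 2 <= ends[np.clip(k, 0, None)])
        for p in pos[inside]:
            rows.append((chrom, int(p)))
    if not rows:
        raise ValueError("no CpGs in retained fragments")
    truth = pd.DataFrame(rows, columns=["chrom", "pos"])
    n = len(truth)

    mix = config.baseline_mixture
    comp = rng.choice(3, size=n, p=list(mix.proportions))
    baseline = np.empty(n)
    for i, (a, b) in enumerate([mix.hyper_beta, mix.hypo_beta, mix.intermediate_beta]):
        m = comp == i
        baseline[m] = rng.beta(a, b, size=int(m.sum()))

    planted = np.zeros(n, dtype=bool)
    direction = np.full(n, "none", dtype=object)
    block_id = np.full(n, -1)
    n_planted = int(round(config.planted_dmc_fraction * n))
    if n_planted > 0:
        n_block_target = int(round(config.planted_block_fraction * n_planted))
        # block planting: runs of consecutive CpGs with gaps <= 100 bp
        chrom_arr = truth["chrom"].to_numpy()
        pos_arr = truth["pos"].to_numpy()
        n_blocked = 0
        bid = 0
        attempts = 0
        while n_blocked < n_block_target and attempts < 50 * max(n_block_target, 1):
            attempts += 1
            size = int(rng.integers(3, 6))
            i = int(rng.integers(0, n - size))
            sl = slice(i, i + size)
            if planted[sl].any():
                continue
            if len(set(chrom_arr[sl])) != 1:
                continue
            if (np.diff(pos_arr[sl]) > 100).any():
                continue
            planted[sl] = True
            d = "hyper_in_group1" if rng.random() < config.hyper_bias else "hypo_in_group1"
            direction[sl] = d
            block_id[sl] = bid
            bid += 1
            n_blocked += size
        n_single = max(n_planted - n_blocked, 0)
        free = np.flatnonzero(~planted)
        singles = rng.choice(free, size=min(n_single, len(free)), replace=False)
        planted[singles] = True
        direction[singles] = np.where(
            rng.random(len(singles)) < config.hyper_bias, "hyper_in_group1", "hypo_in_group1"
        )

    delta = config.effect_size / 100.0
    level_hm = baseline.copy()
    level_mm = baseline.copy()
    adjusted = np.zeros(n, dtype=bool)
    hyper = planted & (direction == "hyper_in_group1")
    hypo = planted & (direction == "hypo_in_group1")
    level_hm[hyper] = baseline[hyper] + delta
    level_hm[hypo] = baseline[hypo] - delta
    # keep the planted difference exactly delta: when the shifted level leaves
    # [0, 1], pin it to the boundary and move the MM level instead
    over = hyper & (level_hm > 1.0)
    level_hm[over] = 1.0
    level_mm[over] = 1.0 - delta
    adjusted |= over
    under = hypo & (level_hm < 0.0)
    level_hm[under] = 0.0
    level_mm[under] = delta
    adjusted |= under

    level_mm16 = level_mm.copy()
    if config.n_age_dmcs > 0:
        free = np.flatnonzero(~planted)
        age_sites = rng.choice(free, size=min(config.n_age_dmcs, len(free)), replace=False)
        level_mm16[age_sites] = np.clip(level_mm16[age_sites] + delta, 0.0, 1.0)

    truth["baseline"] = baseline
    truth["level_hm"] = level_hm
    truth["level_mm15"] = level_mm
    truth["level_mm16"] = level_mm16
    truth["planted_dmc"] = planted
    truth["planted_direction"] = direction
    truth["block_id"] = block_id
    truth["baseline_adjusted"] = adjusted
    return truth.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# --------------------------------------------------------------------- cohort


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """HM bulls sampled at 15 months; MM bulls at 16 months, a subset also at 15
    (paired samples across ages come from the same bull)."""
    rows = []
    for i in range(config.n_hm15):
        rows.append((f"HM15_{i + 1:02d}", f"bullH{i + 1:02d}", "HM", 15))
    n_mm_bulls = max(config.n_mm15, config.n_mm16)
    for i in range(config.n_mm15):
        rows.append((f"MM15_{i + 1:02d}", f"bullM{i + 1:02d}", "MM", 15))
    for i in range(config.n_mm16):
        rows.append((f"MM16_{i + 1:02d}", f"bullM{i + 1:02d}", "MM", 16))
    del n_mm_bulls
    df = pd.DataFrame(rows, columns=["sample_id", "bull_id", "group", "age"])
    df["group_label"] = df["group"] + df["age"].astype(str)
    return df


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    truth: pd.DataFrame
    sheet: pd.DataFrame
    records: dict[str, pd.DataFrame]  # per-sample coverage records (per strand)
    spikeins: pd.DataFrame
    sample_levels: np.ndarray  # sites x samples underlying methylation levels

    @property
    def samples(self) -> list[SampleRecord]:
        return samples_from_sheet(self.sheet)

    def count_matrix(self, merge_strands: bool = True, min_reads: int | None = None) -> CountMatrix:
        from .core import merge_strand_counts

        per_sample = {
            sid: (merge_strand_counts(df) if merge_strands else df)
            for sid, df in self.records.items()
        }
        cm = CountMatrix.from_records(per_sample, self.samples)
        if min_reads is not None:
            cm = cm.filter_cpg10(min_reads)
        return cm


def simulate_sample_counts(
    truth: pd.DataFrame, sheet: pd.DataFrame, config: SimulationConfig, rng=None
) -> SimulatedCohort:
    """Simulate per-sample per-strand bisulfite read counts.

    Coverage per dyad is negative-binomial (mean ``mean_coverage``, size
    ``coverage_dispersion``) and split binomially across strands; methylated
    counts are beta-binomial around a bull-jittered sample-level methylation
    level; unconverted-cytosine errors occur at rate ``1 - conversion_rate``;
    spike-in controls are binomial at the conversion rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(truth)
    bulls = sorted(sheet["bull_id"].unique())
    bull_idx = {b: i for i, b in enumerate(bulls)}
    jitter = rng.normal(0.0, config.bull_jitter_sd, size=(n, len(bulls)))

    level_cols = {"HM15": "level_hm", "HM16": "level_hm", "MM15": "level_mm15", "MM16": "level_mm16"}
    phi = config.biological_dispersion
    conv = config.conversion_rate
    r = config.coverage_dispersion
    p_nb = r / (r + config.mean_coverage)

    records = {}
    spike_rows = []
    sample_levels = np.empty((n, len(sheet)))
    chrom = truth["chrom"].to_numpy()
    pos = truth["pos"].to_numpy()
    for j, row in enumerate(sheet.itertuples(index=False)):
        glevel = truth[level_cols[row.group_label]].to_numpy()
        base = np.clip(glevel, 1e-4, 1 - 1e-4)
        level = expit(logit(base) + jitter[:, bull_idx[row.bull_id]])
        sample_levels[:, j] = level

        cov = rng.negative_binomial(r, p_nb, size=n)
        if phi > 1e-9:
            s = 1.0 / phi - 1.0
            q = rng.beta(np.maximum(level * s, 1e-9), np.maximum((1 - level) * s, 1e-9))
        else:
            q = level
        nf = rng.binomial(cov, 0.5)
        nr = cov - nf
        xf = rng.binomial(nf, q)
        xr = rng.binomial(nr, q)
        if conv < 1.0:
            xf = xf + rng.binomial(nf - xf, 1.0 - conv)
            xr = xr + rng.binomial(nr - xr, 1.0 - conv)
        fwd = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "count_m": xf, "count_u": nf - xf}
        )[nf > 0]
        rev = pd.DataFrame(
            {"chrom": chrom, "pos": pos + 1, "count_m": xr, "count_u": nr - xr}
        )[nr > 0]
        rec = (
            pd.concat([fwd, rev])
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        records[row.sample_id] = rec
        spike_rows.append(
            {
                "sample_id": row.sample_id,
                "converted": int(rng.binomial(config.spikein_cytosines, conv)),
                "total": config.spikein_cytosines,
            }
        )
    return SimulatedCohort(
        config=config,
        truth=truth,
        sheet=sheet,
        records=records,
        spikeins=pd.DataFrame(spike_rows),
        sample_levels=sample_levels,
    )


def simulate_pyro(
    cohort: SimulatedCohort,
    regions: dict[str, list[int]],
    noise_sd: float | None = None,
    rng=None,
) -> pd.DataFrame:
    """Simulate duplicate pyrosequencing percentages for selected regions.

    ``regions`` maps region id -> list of truth-table row indices (CpGs of the
    region, 5'->3').  Each CpG is measured in duplicate per sample with
    Gaussian noise; with probability ``pyro_inconsistent_rate`` the duplicate
    pair is made inconsistent (>5 points apart) and a third, consistent
    replicate is added, exercising the repeat rule.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed + 3)
    if noise_sd is None:
        noise_sd = cohort.config.pyro_noise_sd
    rows = []
    sample_ids = list(cohort.sheet["sample_id"])
    for region_id, site_idx in regions.items():
        order = np.argsort(cohort.truth["pos"].to_numpy()[site_idx])
        for ci, si in enumerate(np.asarray(site_idx)[order]):
            for j, sid in enumerate(sample_ids):
                base = 100.0 * cohort.sample_levels[si, j]
                reps = [
                    base + rng.normal(0, noise_sd),
                    base + rng.normal(0, noise_sd),
                ]
                if rng.random() < cohort.config.pyro_inconsistent_rate:
                    reps[1] = reps[1] + 8.0  # planted inconsistent duplicate
                    reps.append(base + rng.normal(0, noise_sd))
                for k, v in enumerate(reps, start=1):
                    rows.append(
                        {
                            "region": region_id,
                            "cpg_index": ci,
                            "sample_id": sid,
                            "replicate": k,
                            "percentage": float(np.clip(v, 0.0, 100.0)),
                        }
                    )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- drivers


def simulate_cohort(config: SimulationConfig):
    """One-shot driver: genome -> digest -> truth -> counts.

    Returns ``(bundle, fragments, cohort)``.  All randomness derives from
    ``config.seed``; identical configs give identical results.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bundle = generate_toy_genome(config, rng)
    fragments = {
        chrom: digest_mspi(seq, config.frag_min, config.frag_max, internal_only=True)
        for chrom, seq in bundle.sequences.items()
    }
    truth = simulate_methylome(bundle, fragments, config, rng)
    sheet = make_sample_sheet(config)
    cohort = simulate_sample_counts(truth, sheet, config, rng)
    return bundle, fragments, cohort


def write_simulation(bundle: GenomeBundle, cohort: SimulatedCohort, outdir) -> dict:
    """Write every artifact the pipeline consumes; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "cgi_bed": outdir / "cgi.bed",
        "repeat_bed": outdir / "repeats.bed",
        "sample_sheet": outdir / "sample_sheet.csv",
        "spikeins": outdir / "spikeins.csv",
        "truth": outdir / "truth.csv",
        "coverage_dir": covdir,
    }
    _io.write_fasta(bundle.sequences, paths["fasta"])
    _io.write_gtf(bundle.gtf_records, paths["gtf"])
    _io.write_bed(bundle.cgis, paths["cgi_bed"])
    _io.write_bed(bundle.repeats, paths["repeat_bed"], name_col="name")
    _io.write_sample_sheet(cohort.sheet, paths["sample_sheet"])
    cohort.spikeins.to_csv(paths["spikeins"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    for sid, rec in cohort.records.items():
        _io.write_coverage_file(rec, covdir / f"{sid}.cov")
    return {k: str(v) for k, v in paths.items()}
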