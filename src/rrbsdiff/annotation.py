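"""Genomic-context annotation of CpGs, DMCs and DMRs.

Conventions (0-based half-open internally; windows strand-aware):

* gene features, assigned by fixed precedence
  ``TSS > TTS > 5'UTR > 3'UTR > exon > intron > promoter > upstream_10kb >
  downstream_10kb > intergenic`` with any-base overlap:
  TSS window = TSS +/- 100 bp; promoter = -2000..-100 bp upstream of the TSS;
  TTS window = TTS +/- 100 bp; upstream_10kb / downstream_10kb = the 10-kb
  flanks beyond the TSS / TTS.  The precedence is a declared convention of
  this package (gene-body features outrank promoter/upstream so intron/exon
  proportions stay interpretable).
* CpG density: island, shore (up to 2000 bp from an island), shelf (up to
  2000 bp from a shore), else open sea; island/shore/shelf are disjoint after
  derivation.  A region belongs to a class iff at least 75% of its length
  overlaps that class; a single site iff it lies inside.
* repeats: a query is associated with every repeat class overlapping it by at
  least one base.
* gene association: a DMC associates with every gene whose span extended by
  10 kb contains it (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

GENE_FEATURES = [
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
CPG_CONTEXTS = ["island", "shore", "shelf", "open_sea"]
REPEAT_CLASSES = ["LINE", "SINE", "LTR", "satellite", "simple", "other"]

TSS_FLANK = 100
PROMOTER_SPAN = 2000
FLANK_10KB = 10_000
SHORE_BP = 2000
SHELF_BP = 2000
MIN_CONTEXT_OVERLAP = 0.75


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    exons: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        merged = merge_intervals(self.exons)
        return subtract_intervals([(self.start, self.end)], merged)


def load_gene_models(gtf_path) -> list[GeneModel]:
    """Parse gene models from a GTF via gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    for f in db.features_of_type("gene"):
        gid = f.attributes["gene_id"][0]
        genes[gid] = GeneModel(
            gene_id=gid, chrom=f.seqid, strand=f.strand, start=f.start - 1, end=f.end
        )
    for ftype, attr in (("exon", "exons"), ("five_prime_utr", "utr5"), ("three_prime_utr", "utr3")):
        for f in db.features_of_type(ftype):
            gid = f.attributes["gene_id"][0]
            if gid not in genes:  # gene line absent: infer span lazily
                genes[gid] = GeneModel(
                    gene_id=gid, chrom=f.seqid, strand=f.strand, start=f.start - 1, end=f.end
                )
            g = genes[gid]
            getattr(g, attr).append((f.start - 1, f.end))
            g.start = min(g.start, f.start - 1)
            g.end = max(g.end, f.end)
    for g in genes.values():
        g.exons = merge_intervals(g.exons)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


# ----------------------------------------------------------- interval algebra


def merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def subtract_intervals(a, b) -> list[tuple[int, int]]:
    """Set difference a \\ b for merged, sorted interval lists."""
    b = merge_intervals(b)
    out = []
    for s, e in merge_intervals(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def buffer_intervals(intervals, pad: int, chrom_len: int | None = None):
    padded = [
        (max(0, s - pad), e + pad if chrom_len is None else min(chrom_len, e + pad))
        for s, e in intervals
    ]
    return merge_intervals(padded)


def _clip(s: int, e: int, chrom_len: int | None) -> tuple[int, int]:
    s = max(0, s)
    if chrom_len is not None:
        e = min(e, chrom_len)
    return s, e


# ------------------------------------------------------------------- windows


def derive_windows(gene: GeneModel, chrom_len: int | None = None) -> dict[str, list]:
    """Strand-aware per-gene windows: TSS/TTS +/-100 bp, promoter
    -2000..-100 bp of the TSS, and the 10-kb upstream/downstream flanks."""
    t, u = gene.tss, gene.tts
    if gene.strand == "+":
        windows = {
            "TSS": [(t - TSS_FLANK, t + TSS_FLANK + 1)],
            "promoter": [(t - PROMOTER_SPAN, t - TSS_FLANK)],
            "TTS": [(u - TSS_FLANK, u + TSS_FLANK + 1)],
            "upstream_10kb": [(t - FLANK_10KB, t)],
            "downstream_10kb": [(u + 1, u + 1 + FLANK_10KB)],
        }
    else:
        windows = {
            "TSS": [(t - TSS_FLANK, t + TSS_FLANK + 1)],
            "promoter": [(t + TSS_FLANK + 1, t + PROMOTER_SPAN + 1)],
            "TTS": [(u - TSS_FLANK, u + TSS_FLANK + 1)],
            "upstream_10kb": [(t + 1, t + 1 + FLANK_10KB)],
            "downstream_10kb": [(u - FLANK_10KB, u)],
        }
    windows["5'UTR"] = list(gene.utr5)
    windows["3'UTR"] = list(gene.utr3)
    windows["exon"] = list(gene.exons)
    windows["intron"] = gene.introns
    return {
        k: [iv for iv in (_clip(s, e, chrom_len) for s, e in v) if iv[1] > iv[0]]
        for k, v in windows.items()
    }


@dataclass
class ContextTracks:
    """CGI islands with derived, mutually disjoint shores and shelves."""

    islands: dict[str, list]
    shores: dict[str, list]
    shelves: dict[str, list]

    @classmethod
    def from_islands(cls, cgis: pd.DataFrame, chrom_lengths: dict[str, int] | None = None):
        islands, shores, shelves = {}, {}, {}
        chroms = set(cgis["chrom"]) if len(cgis) else set()
        for chrom in chroms:
            cl = (chrom_lengths or {}).get(chrom)
            isl = merge_intervals(
                cgis.loc[cgis["chrom"] == chrom, ["start", "end"]].itertuples(index=False)
            )
            shore_band = subtract_intervals(buffer_intervals(isl, SHORE_BP, cl), isl)
            shelf_band = subtract_intervals(
                buffer_intervals(isl, SHORE_BP + SHELF_BP, cl), buffer_intervals(isl, SHORE_BP, cl)
            )
            islands[chrom] = isl
            shores[chrom] = shore_band
            shelves[chrom] = shelf_band
        return cls(islands, shores, shelves)


class GenomeAnnotation:
    """Bundled gene windows, CpG-density tracks and repeat tracks with
    interval-tree lookups for query annotation."""

    def __init__(
        self,
        genes: list[GeneModel],
        cgis: pd.DataFrame,
        repeats: pd.DataFrame,
        chrom_lengths: dict[str, int] | None = None,
    ):
        self.genes = genes
        self.chrom_lengths = chrom_lengths or {}
        self.tracks = ContextTracks.from_islands(cgis, chrom_lengths)

        self._feature_trees: dict[str, dict[str, IntervalTree]] = {
            f: {} for f in GENE_FEATURES if f != "intergenic"
        }
        for g in genes:
            cl = self.chrom_lengths.get(g.chrom)
            for feat, ivs in derive_windows(g, cl).items():
                tree = self._feature_trees[feat].setdefault(g.chrom, IntervalTree())
                for s, e in ivs:
                    tree.addi(s, e)
        self._context_trees: dict[str, dict[str, IntervalTree]] = {}
        for ctx, track in (
            ("island", self.tracks.islands),
            ("shore", self.tracks.shores),
            ("shelf", self.tracks.shelves),
        ):
            self._context_trees[ctx] = {
                chrom: IntervalTree.from_tuples(ivs) for chrom, ivs in track.items() if ivs
            }
        self._repeat_trees: dict[str, dict[str, IntervalTree]] = {}
        for cls_name, sub in repeats.groupby("name") if len(repeats) else []:
            cls_key = cls_name if cls_name in REPEAT_CLASSES else "other"
            per_chrom = self._repeat_trees.setdefault(cls_key, {})
            for chrom, rows in sub.groupby("chrom"):
                tree = per_chrom.setdefault(chrom, IntervalTree())
                for s, e in rows[["start", "end"]].itertuples(index=False):
                    if e > s:
                        tree.addi(int(s), int(e))
        self._gene_assoc_trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._gene_assoc_trees.setdefault(g.chrom, IntervalTree())
            s, e = _clip(g.start - FLANK_10KB, g.end + FLANK_10KB, self.chrom_lengths.get(g.chrom))
            tree.addi(s, e, g.gene_id)

    @classmethod
    def from_files(cls, gtf_path, cgi_bed, repeat_bed, chrom_lengths=None):
        from . import io as _io

        genes = load_gene_models(gtf_path)
        cgis = _io.read_bed(cgi_bed)
        repeats = _io.read_bed(repeat_bed)
        if "name" not in repeats.columns:
            repeats["name"] = "other"
        return cls(genes, cgis, repeats, chrom_lengths)

    # ------------------------------------------------------------ assignment
    def assign_gene_feature(self, chrom: str, start: int, end: int) -> str:
        """Single gene-feature label by precedence; any-base overlap."""
        for feat in GENE_FEATURES[:-1]:
            tree = self._feature_trees[feat].get(chrom)
            if tree is not None and tree.overlap(start, end):
                return feat
        return "intergenic"

    def assign_cpg_context(self, chrom: str, start: int, end: int) -> str:
        """island/shore/shelf if >= 75% of the query length overlaps the class
        (precedence island > shore > shelf), else open_sea."""
        length = end - start
        if length <= 0:
            raise ValueError("empty query interval")
        for ctx in ("island", "shore", "shelf"):
            tree = self._context_trees.get(ctx, {}).get(chrom)
            if tree is None:
                continue
            ov = sum(min(iv.end, end) - max(iv.begin, start) for iv in tree.overlap(start, end))
            if ov / length >= MIN_CONTEXT_OVERLAP:
                return ctx
        return "open_sea"

    def assign_repeats(self, chrom: str, start: int, end: int) -> set[str]:
        """All repeat classes overlapping the query by at least one base."""
        out = set()
        for cls_name, per_chrom in self._repeat_trees.items():
            tree = per_chrom.get(chrom)
            if tree is not None and tree.overlap(start, end):
                out.add(cls_name)
        return out

    def associate_genes(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene ids whose 10-kb-extended span overlaps the query.  The
        half-open extended interval [gene_start - 10 kb, gene_end + 10 kb)
        makes the base-distance rule inclusive at exactly 10 kb."""
        tree = self._gene_assoc_trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def annotate(self, queries: pd.DataFrame) -> pd.DataFrame:
        """Annotate intervals (columns ``chrom, start, end``; a site is
        ``end = start + 1``).  Returns one row per query with exactly one
        gene_feature, one cpg_context, the overlapping repeat classes and the
        genes within 10 kb."""
        rows = []
        for q in queries.itertuples(index=False):
            reps = self.assign_repeats(q.chrom, q.start, q.end)
            rows.append(
                {
                    "chrom": q.chrom,
                    "start": q.start,
                    "end": q.end,
                    "gene_feature": self.assign_gene_feature(q.chrom, q.start, q.end),
                    "cpg_context": self.assign_cpg_context(q.chrom, q.start, q.end),
                    "repeat_classes": ";".join(sorted(reps)),
                    "genes_within_10kb": ";".join(self.associate_genes(q.chrom, q.start, q.end)),
                }
            )
        return pd.DataFrame(rows)


def associate_genes(
    queries: pd.DataFrame, genes: list[GeneModel], max_distance: int = FLANK_10KB
) -> tuple[dict[str, list[int]], list[str]]:
    """Many-to-many gene association: query index lists per gene plus the
    unique gene list.  A query associates with a gene when its distance to the
    gene span is at most ``max_distance`` (inclusive)."""
    per_gene: dict[str, list[int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for i, q in enumerate(queries.itertuples(index=False)):
        for g in by_chrom.get(q.chrom, []):
            dist = max(g.start - (q.end - 1), q.start - (g.end - 1), 0)
            if dist <= max_distance:
                per_gene.setdefault(g.gene_id, []).append(i)
    return per_gene, sorted(per_gene)


def background_gene_list(
    background_sites: pd.DataFrame, genes: list[GeneModel], max_distance: int = FLANK_10KB
) -> list[str]:
    """Genes with at least one background CpG10 within ``max_distance`` bp —
    the background list for downstream enrichment tools."""
    _, gene_list = associate_genes(background_sites, genes, max_distance)
    return gene_list


def enrichment_vs_background(
    query_ann: pd.DataFrame, background_ann: pd.DataFrame
) -> pd.DataFrame:
    """Per-category relative abundance of the queries against the background.

    Categories: the ten gene features, the four CpG-density contexts, each
    repeat class and ``no_repeat``.  ``flag`` is ``increase`` if the
    query/background ratio exceeds 1.25, ``decrease`` below 0.75, ``equal``
    otherwise, and ``undefined`` when the background proportion is zero.
    """
    rows = []

    def add(category, kind, qp, bp):
        if bp == 0:
            ratio, flag = float("nan"), "undefined"
        else:
            ratio = qp / bp
            flag = "increase" if ratio > 1.25 else ("decrease" if ratio < 0.75 else "equal")
        rows.append(
            {
                "kind": kind,
                "category": category,
                "query_proportion": qp,
                "background_proportion": bp,
                "ratio": ratio,
                "flag": flag,
            }
        )

    nq, nb = len(query_ann), len(background_ann)
    if nq == 0 or nb == 0:
        raise ValueError("empty query or background annotation")
    for feat in GENE_FEATURES:
        add(
            feat,
            "gene_feature",
            (query_ann["gene_feature"] == feat).mean(),
            (background_ann["gene_feature"] == feat).mean(),
        )
    for ctx in CPG_CONTEXTS:
        add(
            ctx,
            "cpg_context",
            (query_ann["cpg_context"] == ctx).mean(),
            (background_ann["cpg_context"] == ctx).mean(),
        )
    q_rep = query_ann["repeat_classes"].fillna("")
    b_rep = background_ann["repeat_classes"].fillna("")
    for cls_name in REPEAT_CLASSES:
        add(
            cls_name,
            "repeat",
            q_rep.str.split(";").apply(lambda xs: cls_name in xs).mean(),
            b_rep.str.split(";").apply(lambda xs: cls_name in xs).mean(),
        )
    add("no_repeat", "repeat", (q_rep == "").mean(), (b_rep == "").mean())
    return pd.DataFrame(rows)
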