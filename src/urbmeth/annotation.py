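"""Genomic feature annotation: CpG islands, shores, gene features, site flags.

Feature classes: promoter (3 kb upstream of the gene start, excluding the TSS
window), tss (-300/+50 around the strand-aware 5' gene start), gene_body,
cgi (sequence-derived CpG islands), cgi_shore (2 kb flanks of islands). A CpG
site carrying none of the five flags is "nonregulatory". All intervals are
0-based half-open, clipped to chromosome bounds; within one gene and class,
overlapping intervals are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

FEATURE_CLASSES = ["promoter", "tss", "gene_body", "cgi", "cgi_shore"]


# ---------------------------------------------------------------------------
# CpG island detection
# ---------------------------------------------------------------------------

def _window_stats(seq: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per non-overlapping window: GC fraction and CpG obs/exp.

    Ambiguous bases count toward window length but not toward GC or CpG;
    obs/exp = (N_CG * L) / (N_C * N_G), defined as 0 when N_C or N_G is 0.
    """
    a = np.frombuffer(seq.upper().encode(), dtype="S1")
    n = len(a) // window
    if n == 0:
        return np.array([]), np.array([])
    trimmed = a[: n * window]
    c = (trimmed == b"C").reshape(n, window).sum(axis=1).astype(float)
    g = (trimmed == b"G").reshape(n, window).sum(axis=1).astype(float)
    cg_pos = (a[:-1] == b"C") & (a[1:] == b"G")
    # a CG pair belongs to the window containing its C
    cg = np.zeros(n)
    idx = np.flatnonzero(cg_pos)
    idx = idx[idx < n * window]
    np.add.at(cg, idx // window, 1)
    gc_frac = (c + g) / window
    denom = c * g
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(denom > 0, cg * window / np.where(denom > 0, denom, 1), 0.0)
    return gc_frac, obs_exp


def detect_cgi(genome: dict[str, str], window: int = 100, n_windows_avg: int = 10,
               min_len: int = 200, gc_min: float = 0.50, obs_exp_min: float = 0.60,
               per_window: bool = False) -> pd.DataFrame:
    """Sliding-window CpG island detection.

    The sequence is cut into non-overlapping ``window`` bp windows. In the
    default (averaged) mode, every stretch of ``n_windows_avg`` consecutive
    windows whose mean GC fraction and mean CpG obs/exp both meet the
    thresholds marks all of its windows as island; the union of marked
    windows is merged into intervals and intervals >= ``min_len`` are
    reported. ``per_window=True`` switches to qualifying each window on its
    own values (no averaging), for sensitivity analysis.
    """
    rows = []
    for chrom in sorted(genome):
        gc_frac, obs_exp = _window_stats(genome[chrom], window)
        n = len(gc_frac)
        if n == 0:
            continue
        marked = np.zeros(n, dtype=bool)
        if per_window:
            marked = (gc_frac >= gc_min) & (obs_exp >= obs_exp_min)
        else:
            w = min(n_windows_avg, n)
            kern = np.ones(w) / w
            gc_avg = np.convolve(gc_frac, kern, mode="valid")
            oe_avg = np.convolve(obs_exp, kern, mode="valid")
            ok = (gc_avg >= gc_min) & (oe_avg >= obs_exp_min)
            for i in np.flatnonzero(ok):
                marked[i:i + w] = True
        # merge runs of marked windows
        padded = np.concatenate([[False], marked, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            length = (e - s) * window
            if length >= min_len:
                rows.append((chrom, int(s * window), int(e * window)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# shores and gene features
# ---------------------------------------------------------------------------

def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome (other columns of
    the first member are kept)."""
    if df.empty:
        return df.reset_index(drop=True)
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None or row.start > cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = row._asdict()
            else:
                cur["end"] = max(cur["end"], row.end)
        out.append(cur)
    return pd.DataFrame(out).reset_index(drop=True)


def make_shores(cgi: pd.DataFrame, chrom_lengths: dict[str, int],
                flank: int = 2000) -> pd.DataFrame:
    """2 kb flanks of each island, excluding bases inside any island."""
    if cgi.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for row in cgi.itertuples(index=False):
        L = chrom_lengths[row.chrom]
        for s, e in ((row.start - flank, row.start), (row.end, row.end + flank)):
            s, e = max(0, s), min(L, e)
            if e > s:
                rows.append((row.chrom, s, e))
    shores = _merge_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    # subtract island bases
    out = []
    cgi_by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in cgi.groupby("chrom")}
    for row in shores.itertuples(index=False):
        pieces = [(row.start, row.end)]
        for cs, ce in cgi_by_chrom.get(row.chrom, []):
            nxt = []
            for s, e in pieces:
                if ce <= s or cs >= e:
                    nxt.append((s, e))
                else:
                    if s < cs:
                        nxt.append((s, cs))
                    if ce < e:
                        nxt.append((ce, e))
            pieces = nxt
        out.extend((row.chrom, s, e) for s, e in pieces if e > s)
    return (pd.DataFrame(out, columns=["chrom", "start", "end"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def derive_gene_features(genes: pd.DataFrame, chrom_lengths: dict[str, int],
                         promoter_bp: int = 3000, tss_upstream: int = 300,
                         tss_downstream: int = 50) -> pd.DataFrame:
    """Strand-aware promoter / tss / gene_body intervals, gene-linked.

    For a + strand gene starting at g: tss = [g-300, g+50), promoter =
    [g-3000, g-300), gene_body = [start, end); mirrored on the - strand.
    Per gene and class, overlapping intervals are merged.
    """
    rows = []
    for gene in genes.itertuples(index=False):
        if gene.end <= gene.start:
            raise ValueError(f"{gene.gene_id}: gene end must exceed start")
        L = chrom_lengths[gene.chrom]

        def clip(s, e):
            return max(0, s), min(L, e)

        if gene.strand == "+":
            g0 = gene.start
            tss = clip(g0 - tss_upstream, g0 + tss_downstream)
            prom = clip(g0 - promoter_bp, g0 - tss_upstream)
        else:
            g0 = gene.end  # 5' end on the - strand
            tss = clip(g0 - tss_downstream, g0 + tss_upstream)
            prom = clip(g0 + tss_upstream, g0 + promoter_bp)
        body = clip(gene.start, gene.end)
        for cls, (s, e) in (("tss", tss), ("promoter", prom), ("gene_body", body)):
            if e > s:
                rows.append((gene.chrom, s, e, cls, gene.strand, gene.gene_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "strand", "gene_id"])
    merged = [ _merge_intervals(grp) for _, grp in df.groupby(["gene_id", "feature"], sort=True) ]
    return (pd.concat(merged, ignore_index=True)
            .sort_values(["chrom", "start", "feature"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# catalog and site annotation
# ---------------------------------------------------------------------------

@dataclass
class FeatureCatalog:
    """Interval sets per feature class plus gene linkage."""

    intervals: pd.DataFrame       # chrom, start, end, feature, gene_id (NA for cgi/shore)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def class_intervals(self, feature: str) -> pd.DataFrame:
        return self.intervals[self.intervals.feature == feature].reset_index(drop=True)

    def trees(self) -> dict[tuple[str, str], IntervalTree]:
        out: dict[tuple[str, str], IntervalTree] = {}
        for row in self.intervals.itertuples(index=False):
            key = (row.chrom, row.feature)
            out.setdefault(key, IntervalTree())
            out[key].addi(row.start, row.end, getattr(row, "gene_id", None))
        return out


def build_catalog(genome: dict[str, str], genes: pd.DataFrame,
                  cgi: pd.DataFrame | None = None, *, promoter_bp: int = 3000,
                  tss_upstream: int = 300, tss_downstream: int = 50,
                  shore_bp: int = 2000, **cgi_kwargs) -> FeatureCatalog:
    """Detect CGIs (unless supplied), derive shores and gene features."""
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    if cgi is None:
        cgi = detect_cgi(genome, **cgi_kwargs)
    shores = make_shores(cgi, chrom_lengths, flank=shore_bp)
    gene_feats = derive_gene_features(genes, chrom_lengths, promoter_bp,
                                      tss_upstream, tss_downstream)
    cgi = cgi.assign(feature="cgi", gene_id=pd.NA)
    shores = shores.assign(feature="cgi_shore", gene_id=pd.NA)
    intervals = pd.concat(
        [gene_feats[["chrom", "start", "end", "feature", "gene_id"]],
         cgi[["chrom", "start", "end", "feature", "gene_id"]],
         shores[["chrom", "start", "end", "feature", "gene_id"]]],
        ignore_index=True)
    return FeatureCatalog(intervals=intervals, chrom_lengths=chrom_lengths)


def annotate_sites(sites: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Point-in-interval flags per feature class plus linked gene ids.

    Returns one row per input site with boolean columns for each class, a
    ``nonregulatory`` flag (no class overlaps) and a ``genes`` column holding
    a sorted tuple of linked gene ids. Sites on chromosomes absent from the
    catalog are annotated nonregulatory with a warning.
    """
    trees = catalog.trees()
    known = set(catalog.chrom_lengths) if catalog.chrom_lengths else \
        {c for c, _ in trees}
    gene_classes = ("promoter", "tss", "gene_body")
    flags = {cls: np.zeros(len(sites), dtype=bool) for cls in FEATURE_CLASSES}
    genes_col: list[tuple] = []
    class_genes_col: dict[str, list[tuple]] = {cls: [] for cls in gene_classes}
    n_unknown = 0
    chroms = sites.chrom.to_numpy()
    poss = sites.pos.to_numpy()
    for i in range(len(sites)):
        chrom, pos = chroms[i], poss[i]
        if known and chrom not in known:
            n_unknown += 1
            genes_col.append(())
            for cls in gene_classes:
                class_genes_col[cls].append(())
            continue
        linked = set()
        for cls in FEATURE_CLASSES:
            tree = trees.get((chrom, cls))
            hits = tree[pos] if tree is not None else set()
            if hits:
                flags[cls][i] = True
            cls_genes = {h.data for h in hits if isinstance(h.data, str)}
            linked.update(cls_genes)
            if cls in gene_classes:
                class_genes_col[cls].append(tuple(sorted(cls_genes)))
        genes_col.append(tuple(sorted(linked)))
    if n_unknown:
        warnings.warn(f"{n_unknown} sites on chromosomes absent from the catalog; "
                      "annotated nonregulatory")
    out = sites.reset_index(drop=True).copy()
    for cls in FEATURE_CLASSES:
        out[cls] = flags[cls]
    out["nonregulatory"] = ~np.logical_or.reduce([flags[c] for c in FEATURE_CLASSES])
    out["genes"] = genes_col
    for cls in gene_classes:  # gene links resolved per class (for the expression model)
        out[f"genes_{cls}"] = class_genes_col[cls]
    return out


def read_gene_models(path) -> pd.DataFrame:
    """Read BED6 gene models (chrom, start, end, gene_id, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "score", "strand"],
                     dtype={"chrom": str, "gene_id": str})
    if not set(df.strand) <= {"+", "-"}:
        raise ValueError("strand column must be + or -")
    return df
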