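"""Over-representation analyses.

Three designs, all against bespoke backgrounds:

* feature enrichment — 2x2 tables of DMSs vs the relaxed genome-wide CpG
  background, in/out of a feature class, with the cross-product odds ratio
  and a two-sided Fisher exact p;
* expressed-gene enrichment — the property is being linked (via promoter,
  TSS or gene body) to at least one expressed gene; optionally restricted to
  DMSs inside DMRs, with a background of CpG sites lying within 2 kb of two
  or more other sites;
* GO term over-representation — one-sided hypergeometric tests for genes
  linked to DMR-member DMSs, annotations propagated to ancestors through
  is_a/part_of edges (true-path rule), BH-corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# 2x2 machinery
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """A 2x2 focal-vs-background contingency with odds ratio and exact p.

    a = focal with the property, b = focal without, c = background with,
    d = background without. odds_ratio is the sample cross-product (a/b)/(c/d);
    a zero b or c makes it infinite (flagged degenerate), a zero a or d makes
    it zero or undefined likewise.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    direction: str
    degenerate: bool = False

    @classmethod
    def from_counts(cls, label: str, a: int, b: int, c: int, d: int) -> "EnrichmentResult":
        if min(a, b, c, d) < 0:
            raise ValueError("counts must be non-negative")
        if (a + b) == 0 or (c + d) == 0:
            raise ValueError(f"{label}: empty focal or background set")
        num, den = a * d, b * c
        degenerate = (num == 0) or (den == 0)
        if den > 0:
            odds = num / den
        elif num > 0:
            odds = math.inf
        else:
            odds = math.nan
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        direction = "over" if odds > 1 else "under"
        return cls(label, a, b, c, d, odds, p, direction, degenerate)

    def swap(self) -> "EnrichmentResult":
        """Focal and background exchanged (odds ratio inverts, p unchanged)."""
        return EnrichmentResult.from_counts(self.label + " (swapped)",
                                            self.c, self.d, self.a, self.b)


def feature_enrichment(dms_annotation: pd.DataFrame, background_annotation: pd.DataFrame,
                       feature_class: str) -> EnrichmentResult:
    """DMS in/out of a feature class against the background annotation.

    ``feature_class`` may be any boolean column of the annotation frames
    ("promoter", "tss", "gene_body", "cgi", "cgi_shore", "nonregulatory") or
    "regulatory" (the complement of nonregulatory). The DMS set is not
    excluded from the background.
    """
    def in_class(ann: pd.DataFrame) -> np.ndarray:
        if feature_class == "regulatory":
            return ~ann.nonregulatory.to_numpy()
        return ann[feature_class].to_numpy()

    f = in_class(dms_annotation)
    g = in_class(background_annotation)
    return EnrichmentResult.from_counts(
        feature_class, int(f.sum()), int((~f).sum()), int(g.sum()), int((~g).sum()))


# ---------------------------------------------------------------------------
# expressed genes
# ---------------------------------------------------------------------------

def expressed_gene_flag(counts: pd.DataFrame, min_count: int = 10,
                        min_fraction: float = 0.25) -> pd.Series:
    """Expressed iff raw count >= min_count in >= ceil(min_fraction * n) samples."""
    n_needed = math.ceil(min_fraction * counts.shape[1])
    return (counts >= min_count).sum(axis=1) >= n_needed


def _linked_to_expressed(annotation: pd.DataFrame, expressed: pd.Series,
                         missing_warn: list | None = None) -> np.ndarray:
    """Per site: linked via promoter/TSS/gene body to >=1 expressed gene."""
    out = np.zeros(len(annotation), dtype=bool)
    gene_linked = (annotation.promoter | annotation.tss | annotation.gene_body).to_numpy()
    for i, genes in enumerate(annotation.genes):
        if not gene_linked[i]:
            continue
        for g in genes:
            if g not in expressed.index:
                if missing_warn is not None:
                    missing_warn.append(g)
                continue
            if expressed[g]:
                out[i] = True
                break
    return out


def sites_with_neighbors(sites: pd.DataFrame, window: int = 2000,
                         min_neighbors: int = 2) -> np.ndarray:
    """Sites lying, with >= min_neighbors other sites, inside one window-span.

    Uses the same span convention as the DMR caller: a site qualifies when it
    belongs to some run of (min_neighbors + 1) consecutive sites whose first-
    to-last span (inclusive) is at most ``window``.
    """
    k = min_neighbors  # run length k+1
    out = np.zeros(len(sites), dtype=bool)
    order = sites.sort_values(["chrom", "pos"]).index.to_numpy()
    sorted_sites = sites.loc[order]
    offset = 0
    for chrom, grp in sorted_sites.groupby("chrom", sort=True):
        pos = grp.pos.to_numpy()
        n = len(pos)
        qual = np.zeros(n, dtype=bool)
        if n >= k + 1:
            span_ok = (pos[k:] - pos[:-k] + 1) <= window  # run starting at i
            for i in np.flatnonzero(span_ok):
                qual[i:i + k + 1] = True
        out[order[offset:offset + n]] = qual
        offset += n
    return out


def expression_enrichment(dms_annotation: pd.DataFrame,
                          background_annotation: pd.DataFrame,
                          expressed: pd.Series, *, dmr_restricted: bool = False,
                          dms_in_dmr: np.ndarray | None = None,
                          window: int = 2000) -> EnrichmentResult:
    """Are DMSs linked to expressed genes more often than background sites?

    With ``dmr_restricted`` the focal set is the DMSs inside DMRs (mask
    required) and the background is restricted to CpG sites located within
    2 kb of two or more other background sites.
    """
    focal = dms_annotation
    background = background_annotation
    label = "expressed_genes"
    if dmr_restricted:
        if dms_in_dmr is None:
            raise ValueError("dmr_restricted requires the dms_in_dmr mask")
        focal = dms_annotation[np.asarray(dms_in_dmr, dtype=bool)]
        background = background_annotation[
            sites_with_neighbors(background_annotation[["chrom", "pos"]], window=window)]
        label = "expressed_genes_dmr_restricted"
    if len(focal) == 0:
        raise ValueError("focal set is empty")
    f = _linked_to_expressed(focal, expressed)
    g = _linked_to_expressed(background, expressed)
    return EnrichmentResult.from_counts(
        label, int(f.sum()), int((~f).sum()), int(g.sum()), int((~g).sum()))


# ---------------------------------------------------------------------------
# GO over-representation
# ---------------------------------------------------------------------------

def propagate_annotations(gene_terms: pd.DataFrame, ontology: nx.MultiDiGraph
                          ) -> dict[str, set]:
    """gene -> set of terms, closed over is_a/part_of ancestors (true-path)."""
    keep = {"is_a", "part_of"}
    sub = nx.MultiDiGraph()
    sub.add_nodes_from(ontology.nodes)
    sub.add_edges_from((u, v, k) for u, v, k in ontology.edges(keys=True) if k in keep)
    cache: dict[str, set] = {}

    def ancestors(t: str) -> set:
        if t not in cache:
            cache[t] = nx.descendants(sub, t) if t in sub else set()
        return cache[t]

    out: dict[str, set] = {}
    for row in gene_terms.itertuples(index=False):
        if row.term not in ontology:
            continue
        s = out.setdefault(row.gene_id, set())
        s.add(row.term)
        s |= ancestors(row.term)
    return out


def go_enrichment(focal_genes, background_genes, gene_terms: pd.DataFrame,
                  ontology: nx.MultiDiGraph, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per GO term.

    N = background genes, K = background genes annotated to the term (after
    true-path propagation), n = focal genes, k = focal genes annotated.
    Terms with k >= 1 are tested; p = P(X >= k) under Hypergeom(N, K, n);
    BH correction across tested terms. Genes without any annotation count in
    N and n but contribute to no term.
    """
    focal = sorted(set(focal_genes))
    background = sorted(set(background_genes) | set(focal))
    ann = propagate_annotations(gene_terms, ontology)
    names = {t: (ontology.nodes[t].get("name", t) if t in ontology else t)
             for t in {term for s in ann.values() for term in s}}
    N, n = len(background), len(focal)
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for g in background:
        for t in ann.get(g, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
    for g in focal:
        for t in ann.get(g, ()):
            term_fg[t] = term_fg.get(t, 0) + 1
    rows = []
    for t, k in term_fg.items():
        K = term_bg[t]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((t, names.get(t, t), k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p_value"])
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["fdr"] = multipletests(out.p_value, method="fdr_bh")[1]
    out["significant"] = out.fdr < fdr_threshold
    return out.sort_values(["p_value", "term"]).reset_index(drop=True)
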