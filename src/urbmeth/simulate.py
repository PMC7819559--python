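"""Synthetic two-habitat RRBS + expression data generator.

Emulates the statistical structure the downstream analysis assumes: a
CpG-suppressed background genome with planted CpG islands, per-sample
Bismark-style per-cytosine counts at real CG dinucleotides (both strands),
a mostly hypomethylated baseline, a planted set of sites with >25-point
between-habitat shifts (some clustered within 2 kb, some inside gene TSS
windows), and gene expression counts negatively coupled to TSS methylation.

Every generated quantity is recorded in a :class:`GroundTruth` bundle so the
full pipeline can be scored for parameter recovery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _background_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """CpG-depleted background: GC ~= 40%, CpG obs/exp ~= 0.25-0.3.

    Letters are drawn iid and 75% of CG dinucleotides are then destroyed by
    replacing the G with A or T; CG pairs cannot overlap and the replacement
    letters cannot create new pairs, so one pass suffices.
    """
    seq = rng.choice(BASES, size=length, p=[0.285, 0.20, 0.23, 0.285])
    cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
    kill = cg[rng.random(cg.size) > 0.25]
    seq[kill + 1] = rng.choice(np.array(["A", "T"]), size=kill.size)
    return seq


def _island_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    # GC ~= 66%, obs/exp ~= 1.0: clears the detection thresholds with margin
    return rng.choice(BASES, size=length, p=[0.17, 0.33, 0.33, 0.17])


def generate_genome(config: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[dict[str, str], pd.DataFrame]:
    """Return ``{chrom: sequence}`` and the planted CGI truth intervals.

    Islands are placed in evenly spaced slots with >=2 kb clearance from the
    chromosome ends and from each other; a slot whose placement would overflow
    is retried a bounded number of times before raising.
    """
    config.validate()
    genome: dict[str, str] = {}
    cgi_rows = []
    L, ilen = config.chrom_length_bp, config.cgi_length_bp
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = _background_sequence(L, rng)
        n = config.n_cgi
        if n > 0:
            slot = L // n
            if slot < ilen + 4000:
                raise ValueError("chromosome too short for requested islands")
            for i in range(n):
                for _ in range(100):  # bounded retries
                    lo = i * slot + 2000
                    hi = (i + 1) * slot - 2000 - ilen
                    if hi <= lo:
                        continue
                    start = int(rng.integers(lo, hi))
                    break
                else:
                    raise RuntimeError("could not place CpG island")
                seq[start:start + ilen] = _island_sequence(ilen, rng)
                cgi_rows.append((chrom, start, start + ilen))
        genome[chrom] = "".join(seq)
    cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    return genome, cgi


def cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the + strand C of every CG dinucleotide."""
    a = np.frombuffer(seq.encode(), dtype="S1")
    return np.flatnonzero((a[:-1] == b"C") & (a[1:] == b"G"))


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def generate_gene_models(config: SimulationConfig, genome: dict[str, str],
                         rng: np.random.Generator) -> pd.DataFrame:
    """BED6-like gene models with a hidden expressed/non-expressed truth flag.

    Genes are placed in evenly spaced slots (3.5 kb clearance for promoter
    room), lengths Uniform(1, 3) kb, strands random.
    """
    chroms = list(genome)
    rows = []
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    g = 0
    for chrom in chroms:
        L = len(genome[chrom])
        slot = L // per_chrom
        for i in range(per_chrom):
            if g >= config.n_genes:
                break
            length = int(rng.integers(1000, 3001))
            # 400 bp slot margins keep adjacent genes >= 800 bp apart, so TSS
            # windows of neighbouring genes never overlap
            lo = max(i * slot + 400, 3500)
            hi = min((i + 1) * slot - 400, L - 3500) - length
            if hi <= lo:
                raise ValueError("chromosome too short for requested genes")
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, start, start + length, f"gene{g + 1:04d}", 0, strand))
            g += 1
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])
    n_expr = int(round((1 - config.nonexpressed_fraction) * len(genes)))
    expressed = np.zeros(len(genes), dtype=bool)
    expressed[rng.choice(len(genes), size=n_expr, replace=False)] = True
    genes["expressed_truth"] = expressed
    return genes


def _tss_window(gene: pd.Series, up: int = 300, down: int = 50) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.start - up, gene.start + down
    return gene.end - down, gene.end + up


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted parameters, for recovery scoring."""

    true_dms: pd.DataFrame          # chrom,pos,p_urban,p_forest,effect,direction,cluster_id,gene_id
    true_dmrs: pd.DataFrame         # chrom,start,end,n_sites,cluster_id
    cgi: pd.DataFrame               # chrom,start,end
    genes: pd.DataFrame             # gene models incl. expressed_truth
    site_props: pd.DataFrame        # chrom,pos,p_urban,p_forest for every CpG unit
    n_clipped: int = 0


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: pd.DataFrame
    samples: pd.DataFrame                       # sample_id, habitat, tissue
    strand_counts: dict[str, pd.DataFrame]      # per sample: chrom,pos,meth,total (strand-level)
    truth: GroundTruth
    expression: pd.DataFrame | None = None      # genes x samples raw counts
    ontology_obo: str | None = None
    gene_terms: pd.DataFrame | None = None      # gene_id, term


def _sample_ids(config: SimulationConfig) -> pd.DataFrame:
    ids = [f"urban_{i+1}" for i in range(config.n_per_group)] + \
          [f"forest_{i+1}" for i in range(config.n_per_group)]
    habitat = ["urban"] * config.n_per_group + ["forest"] * config.n_per_group
    return pd.DataFrame({"sample_id": ids, "habitat": habitat, "tissue": "liver"})


def generate_methylomes(config: SimulationConfig, genome: dict[str, str],
                        genes: pd.DataFrame, rng: np.random.Generator
                        ) -> tuple[dict[str, pd.DataFrame], GroundTruth, pd.DataFrame]:
    """Per-sample strand-level CpG counts plus the planted ground truth.

    Per CpG unit and sample, each strand's read total is NB(mean/2, disp/2)
    (so the destranded total is NB(mean, disp)) and methylated reads are
    Binomial(total, p_group).
    """
    config.validate()
    unit_rows = []
    for chrom, seq in genome.items():
        pos = cpg_positions(seq)
        unit_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    units = pd.concat(unit_rows, ignore_index=True)
    n_units = len(units)
    if config.n_true_dms > n_units:
        raise ValueError("n_true_dms exceeds the number of CpG sites in the genome")

    base = rng.beta(config.beta_a, config.beta_b, size=n_units)
    p_urban = base.copy()
    p_forest = base.copy()

    # --- choose planted sites -------------------------------------------------
    n_clustered = 3 * (int(round(config.n_true_dms * config.dmr_fraction)) // 3)
    n_clusters = n_clustered // 3
    n_tss = min(config.n_tss_dms, config.n_true_dms - n_clustered)
    n_single = config.n_true_dms - n_clustered - n_tss

    taken = np.zeros(n_units, dtype=bool)
    pos_arr = units["pos"].to_numpy()
    chrom_arr = units["chrom"].to_numpy()

    # clusters and free singletons stay out of TSS windows so the planted
    # TSS-expression coupling is exactly the configured slope
    in_tss = np.zeros(n_units, dtype=bool)
    for _, gene in genes.iterrows():
        lo, hi = _tss_window(gene)
        in_tss |= (chrom_arr == gene.chrom) & (pos_arr >= lo) & (pos_arr < hi)

    planted: list[tuple[int, int, str | None]] = []  # (unit index, cluster_id, gene_id)

    def _too_close(idx: int, margin: int = 6000) -> bool:
        lo = np.searchsorted(pos_arr, pos_arr[idx] - margin)
        hi = np.searchsorted(pos_arr, pos_arr[idx] + margin)
        same = chrom_arr[lo:hi] == chrom_arr[idx]
        return bool(taken[lo:hi][same].any())

    # 2 kb clusters of three consecutive CpG units
    cid = 0
    attempts = 0
    while cid < n_clusters:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place DMS clusters")
        i = int(rng.integers(0, n_units - 3))
        if chrom_arr[i] != chrom_arr[i + 2]:
            continue
        if pos_arr[i + 2] - pos_arr[i] + 1 > 1800:
            continue
        if in_tss[i:i + 3].any() or any(_too_close(j) for j in (i, i + 1, i + 2)):
            continue
        cid += 1
        for j in (i, i + 1, i + 2):
            taken[j] = True
            planted.append((j, cid, None))

    # TSS-linked singletons, in truth-expressed genes only
    tss_genes = genes[genes.expressed_truth].sample(frac=1.0, random_state=int(rng.integers(2**31)))
    n_placed = 0
    for _, gene in tss_genes.iterrows():
        if n_placed >= n_tss:
            break
        # upstream portion of the TSS window only, keeping the planted site
        # out of the gene body (whose slope should stay at zero)
        if gene.strand == "+":
            lo, hi = gene.start - 300, gene.start
        else:
            lo, hi = gene.end, gene.end + 300
        sel = np.flatnonzero((chrom_arr == gene.chrom) & (pos_arr >= lo) & (pos_arr < hi))
        sel = [j for j in sel if not _too_close(j)]
        if not sel:
            continue
        j = int(rng.choice(sel))
        taken[j] = True
        planted.append((j, 0, gene.gene_id))
        n_placed += 1

    # unconstrained singletons
    n_single += n_tss - n_placed
    while n_single > 0:
        j = int(rng.integers(0, n_units))
        if in_tss[j] or _too_close(j):
            continue
        taken[j] = True
        planted.append((j, 0, None))
        n_single -= 1

    # --- apply shifts ---------------------------------------------------------
    eff = config.true_effect
    dms_rows = []
    n_clipped = 0
    for j, cluster_id, gene_id in planted:
        hyper = rng.random() < config.hyper_fraction
        if hyper:
            pf = rng.uniform(0.05, min(0.60, 0.99 - eff))
            pu = pf + eff
        else:
            pf = rng.uniform(max(0.40, eff + 0.01), 0.95)
            pu = pf - eff
        pu_c, pf_c = np.clip([pu, pf], 0.01, 0.99)
        if (pu_c, pf_c) != (pu, pf):
            n_clipped += 1
        realized = pu_c - pf_c
        p_urban[j], p_forest[j] = pu_c, pf_c
        if abs(realized) > 0.25:  # clipped sites only count as truth if still >25 pts
            dms_rows.append((chrom_arr[j], int(pos_arr[j]), pu_c, pf_c, realized,
                             "hyper" if realized > 0 else "hypo", cluster_id, gene_id))
    true_dms = pd.DataFrame(
        dms_rows, columns=["chrom", "pos", "p_urban", "p_forest", "effect",
                           "direction", "cluster_id", "gene_id"],
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)

    dmr_rows = []
    for cluster_id, grp in true_dms[true_dms.cluster_id > 0].groupby("cluster_id"):
        if len(grp) >= 3:
            dmr_rows.append((grp.chrom.iloc[0], int(grp.pos.min()),
                             int(grp.pos.max()) + 1, len(grp), cluster_id))
    true_dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "n_sites", "cluster_id"])

    # --- draw counts ----------------------------------------------------------
    samples = _sample_ids(config)
    size = config.coverage_dispersion / 2.0
    nb_p = size / (size + config.coverage_mean / 2.0)
    strand_counts: dict[str, pd.DataFrame] = {}
    for _, s in samples.iterrows():
        p = p_urban if s.habitat == "urban" else p_forest
        frames = []
        for strand_off in (0, 1):  # + strand C at pos, - strand C at pos+1
            total = rng.negative_binomial(size, nb_p, size=n_units)
            meth = rng.binomial(total, p)
            frames.append(pd.DataFrame({
                "chrom": chrom_arr, "pos": pos_arr + strand_off,
                "meth": meth, "total": total,
            }))
        df = pd.concat(frames, ignore_index=True)
        df = df[df.total > 0].sort_values(["chrom", "pos"]).reset_index(drop=True)
        strand_counts[s.sample_id] = df

    site_props = units.assign(p_urban=p_urban, p_forest=p_forest)
    truth = GroundTruth(true_dms=true_dms, true_dmrs=true_dmrs,
                        cgi=pd.DataFrame(columns=["chrom", "start", "end"]),
                        genes=genes, site_props=site_props, n_clipped=n_clipped)
    return strand_counts, truth, samples


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(config: SimulationConfig, genes: pd.DataFrame,
                        strand_counts: dict[str, pd.DataFrame],
                        truth: GroundTruth, samples: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Gene x sample raw counts, negatively coupled to TSS methylation.

    Expressed genes get a baseline log2 mean in ``expression_log2_mean_range``
    (TSS-DMS genes from the upper half of the range so the coupling never
    pushes them below the expressed-gene detection rule); genes carrying a
    planted TSS DMS have each sample's log2 mean shifted by
    ``expression_tss_slope`` x realised methylation % of that sample at the
    planted site. Non-expressed genes get a mean of ~1.4 counts.
    """
    lo, hi = config.expression_log2_mean_range
    tss_gene_site = {g: (c, p) for c, p, g in
                     truth.true_dms.loc[truth.true_dms.gene_id.notna(),
                                        ["chrom", "pos", "gene_id"]].itertuples(index=False)}

    # realised merged methylation % per planted TSS site and sample
    meth_pct: dict[str, dict[str, float]] = {}
    for sid, df in strand_counts.items():
        by = {}
        for g, (c, p) in tss_gene_site.items():
            sel = df[(df.chrom == c) & df.pos.isin((p, p + 1))]
            t = sel.total.sum()
            by[g] = 100.0 * sel.meth.sum() / t if t > 0 else 0.0
        meth_pct[sid] = by

    counts = np.zeros((len(genes), len(samples)), dtype=int)
    for gi, gene in genes.reset_index(drop=True).iterrows():
        if not gene.expressed_truth:
            base = 0.5
        elif gene.gene_id in tss_gene_site:
            base = rng.uniform((lo + hi) / 2, hi)
        else:
            base = rng.uniform(lo, hi)
        for si, sid in enumerate(samples.sample_id):
            mu_log2 = base
            if gene.gene_id in tss_gene_site and gene.expressed_truth:
                mu_log2 = base + config.expression_tss_slope * meth_pct[sid][gene.gene_id]
            mean = 2.0 ** mu_log2
            size = config.expression_dispersion
            counts[gi, si] = rng.negative_binomial(size, size / (size + mean))
    return pd.DataFrame(counts, index=genes.gene_id.to_numpy(), columns=samples.sample_id.to_numpy())


# ---------------------------------------------------------------------------
# toy ontology
# ---------------------------------------------------------------------------

def generate_ontology(genes: pd.DataFrame, rng: np.random.Generator,
                      n_branches: int = 4, leaves_per_branch: int = 4
                      ) -> tuple[str, pd.DataFrame]:
    """A small is_a/part_of DAG in OBO format plus a random gene->leaf mapping."""
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: toy\n\n")
    buf.write("[Term]\nid: GO:0000001\nname: biological_process\n\n")
    leaf_ids = []
    tid = 1
    for b in range(n_branches):
        tid += 1
        mid = f"GO:{tid:07d}"
        buf.write(f"[Term]\nid: {mid}\nname: branch_{b + 1}\nis_a: GO:0000001\n\n")
        for l in range(leaves_per_branch):
            tid += 1
            leaf = f"GO:{tid:07d}"
            buf.write(f"[Term]\nid: {leaf}\nname: leaf_{b + 1}_{l + 1}\nis_a: {mid}\n")
            if l == 0 and b > 0:  # a few part_of cross links
                buf.write(f"relationship: part_of GO:{(tid - leaves_per_branch - 1):07d}\n")
            buf.write("\n")
            leaf_ids.append(leaf)
    rows = []
    for gid in genes.gene_id:
        k = int(rng.integers(1, 4))
        for t in rng.choice(leaf_ids, size=k, replace=False):
            rows.append((gid, t))
    return buf.getvalue(), pd.DataFrame(rows, columns=["gene_id", "term"])


# ---------------------------------------------------------------------------
# bundle + disk round trip
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate the complete in-memory dataset; deterministic given the seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    genome, cgi = generate_genome(config, rng)
    genes = generate_gene_models(config, genome, rng)
    strand_counts, truth, samples = generate_methylomes(config, genome, genes, rng)
    truth.cgi = cgi
    expression = generate_expression(config, genes, strand_counts, truth, samples, rng)
    obo, gene_terms = generate_ontology(genes, rng)
    return SimulatedDataset(config=config, genome=genome, genes=genes, samples=samples,
                            strand_counts=strand_counts, truth=truth, expression=expression,
                            ontology_obo=obo, gene_terms=gene_terms)


def coverage_frame(strand_df: pd.DataFrame) -> pd.DataFrame:
    """Strand-level counts -> Bismark coverage dialect (1-based inclusive)."""
    pct = 100.0 * strand_df.meth / strand_df.total
    return pd.DataFrame({
        "chrom": strand_df.chrom, "start": strand_df.pos + 1, "end": strand_df.pos + 1,
        "pct": pct.round(6), "meth": strand_df.meth, "unmeth": strand_df.total - strand_df.meth,
    })


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, BED6 gene models, per-sample coverage files, expression,
    ontology and truth tables; returns the path map."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    recs = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in ds.genome.items()]
    SeqIO.write(recs, paths["genome"], "fasta")

    paths["genes"] = out / "genes.bed"
    ds.genes[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        paths["genes"], sep="\t", header=False, index=False)

    rows = []
    for _, s in ds.samples.iterrows():
        p = out / f"{s.sample_id}.cov"
        coverage_frame(ds.strand_counts[s.sample_id]).to_csv(p, sep="\t", header=False, index=False)
        rows.append((s.sample_id, s.habitat, s.tissue, p.name))  # path relative to samples.tsv
    paths["samples"] = out / "samples.tsv"
    pd.DataFrame(rows, columns=["sample_id", "habitat", "tissue", "path"]).to_csv(
        paths["samples"], sep="\t", index=False)

    paths["expression"] = out / "expression.tsv"
    ds.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")

    paths["ontology"] = out / "ontology.obo"
    paths["ontology"].write_text(ds.ontology_obo)
    paths["gene_terms"] = out / "go_annotation.tsv"
    ds.gene_terms.to_csv(paths["gene_terms"], sep="\t", index=False)

    t = ds.truth
    for name, df in [("true_dms", t.true_dms), ("true_dmrs", t.true_dmrs),
                     ("true_cgi", t.cgi), ("site_props", t.site_props),
                     ("gene_truth", t.genes)]:
        paths[name] = out / f"truth_{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    return paths
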