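"""Bismark-style coverage IO, CpG destranding, coverage filters and uniting.

Internally all coordinates are 0-based half-open; the Bismark coverage dialect
(1-based inclusive) is translated at the file boundary. A "CpG unit" is the
destranded dinucleotide, keyed by the position of its + strand cytosine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

COVERAGE_COLUMNS = ["chrom", "pos", "meth", "total"]


class CoverageFormatError(ValueError):
    pass


def read_coverage(path) -> pd.DataFrame:
    """Read a 6-column Bismark coverage file into (chrom, pos, meth, total).

    Positions are converted to 0-based; zero-coverage rows are dropped. A
    reported percentage inconsistent with the counts by more than 0.5 points
    triggers a warning (counts are trusted); malformed lines raise with their
    line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment=None,
                         names=["chrom", "start", "end", "pct", "meth", "unmeth"],
                         dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CoverageFormatError(f"{path}: cannot parse coverage file: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=COVERAGE_COLUMNS)
    for col in ("start", "end", "meth", "unmeth"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise CoverageFormatError(
                f"{path}: malformed line {int(np.flatnonzero(bad)[0]) + 1}")
        df[col] = df[col].astype(np.int64)
    if (df.meth < 0).any() or (df.unmeth < 0).any():
        raise CoverageFormatError(f"{path}: negative read counts")
    total = df.meth + df.unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * df.meth / total.replace(0, np.nan)
    off = (pct - pd.to_numeric(df.pct, errors="coerce")).abs()
    if (off > 0.5).any():
        warnings.warn(f"{path}: {int((off > 0.5).sum())} rows with methylation % "
                      "inconsistent with counts; counts trusted")
    out = pd.DataFrame({"chrom": df.chrom, "pos": df.start - 1,
                        "meth": df.meth, "total": total})
    return out[out.total > 0].reset_index(drop=True)


def merge_strands(sites: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """Sum the two strand records of each CpG dinucleotide into one unit.

    A record at the + strand C position p and one at p+1 (the - strand C,
    reported at its G) become a single unit at p. Records whose position is
    not in CpG context pass through unmerged; their number is reported in a
    warning.
    """
    if sites.empty:
        return pd.DataFrame(columns=COVERAGE_COLUMNS)
    frames = []
    n_noncpg = 0
    for chrom, df in sites.groupby("chrom", sort=True):
        seq = genome.get(chrom)
        if seq is None:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        pos = df.pos.to_numpy()
        if (pos < 0).any() or (pos >= len(seq)).any():
            raise ValueError(f"{chrom}: position beyond chromosome end")
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_plus_c = (arr[pos] == b"C") & (pos + 1 < len(seq)) & (arr[np.minimum(pos + 1, len(seq) - 1)] == b"G")
        is_minus_c = (arr[pos] == b"G") & (pos - 1 >= 0) & (arr[np.maximum(pos - 1, 0)] == b"C")
        unit = np.where(is_plus_c, pos, np.where(is_minus_c, pos - 1, pos))
        n_noncpg += int((~is_plus_c & ~is_minus_c).sum())
        g = (pd.DataFrame({"pos": unit, "meth": df.meth.to_numpy(),
                           "total": df.total.to_numpy()})
             .groupby("pos", as_index=False).sum())
        g.insert(0, "chrom", chrom)
        frames.append(g)
    if n_noncpg:
        warnings.warn(f"{n_noncpg} records outside CpG context passed through unmerged")
    return pd.concat(frames, ignore_index=True)


def filter_coverage(sites: pd.DataFrame, min_coverage: int = 10,
                    max_quantile: float = 0.999) -> pd.DataFrame:
    """Keep sites with min_coverage <= total <= this sample's coverage quantile.

    The cap removes totals strictly above the (linear-interpolation) quantile;
    sites equal to it are retained.
    """
    if sites.empty:
        return sites.copy()
    cap = float(np.quantile(sites.total.to_numpy(), max_quantile))
    keep = (sites.total >= min_coverage) & (sites.total <= cap)
    return sites[keep].reset_index(drop=True)


@dataclass
class MethylationMatrix:
    """United CpG units x samples with methylated/total read counts.

    ``sites`` is ordered by (chrom, pos); ``meth`` and ``total`` are
    (n_sites, n_samples) integer arrays aligned to ``samples`` rows.
    """

    sites: pd.DataFrame       # chrom, pos (0-based unit)
    meth: np.ndarray
    total: np.ndarray
    samples: pd.DataFrame     # sample_id, habitat, tissue

    def __post_init__(self):
        if (self.meth > self.total).any() or (self.meth < 0).any():
            raise ValueError("methylated counts must lie in [0, total]")
        habs = set(self.samples.habitat)
        if not {"urban", "forest"} <= habs:
            raise ValueError("both habitats must be present")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def fractions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)

    def habitat_mask(self, habitat: str) -> np.ndarray:
        return (self.samples.habitat == habitat).to_numpy()

    def to_tsv(self, path) -> None:
        df = self.sites.copy()
        df["pos_1based"] = df.pos + 1
        for j, sid in enumerate(self.samples.sample_id):
            df[f"{sid}.nM"] = self.meth[:, j]
            df[f"{sid}.nT"] = self.total[:, j]
        df.drop(columns="pos").to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        sites = pd.DataFrame({"chrom": df.chrom, "pos": df.pos_1based - 1})
        meth = np.column_stack([df[f"{s}.nM"] for s in samples.sample_id])
        total = np.column_stack([df[f"{s}.nT"] for s in samples.sample_id])
        return cls(sites=sites, meth=meth, total=total, samples=samples.reset_index(drop=True))


def unite(sample_sites: dict[str, pd.DataFrame], samples: pd.DataFrame,
          min_coverage: int = 10, max_quantile: float = 0.999,
          prefiltered: bool = False) -> MethylationMatrix:
    """Intersect per-sample (destranded) sites into one matrix.

    Coverage filtering is applied per sample first unless ``prefiltered``;
    the retained site set is the intersection across all samples, ordered by
    (chrom, pos).
    """
    samples = samples.reset_index(drop=True)
    for hab in ("urban", "forest"):
        if (samples.habitat == hab).sum() < 2:
            raise ValueError("need at least two samples per habitat")
    filtered = {}
    for sid in samples.sample_id:
        df = sample_sites[sid]
        if not prefiltered:
            df = filter_coverage(df, min_coverage, max_quantile)
        filtered[sid] = df.set_index(["chrom", "pos"])
    common = None
    for df in filtered.values():
        idx = df.index
        common = idx if common is None else common.intersection(idx)
    if common is None or len(common) == 0:
        raise ValueError("no CpG site is covered in all samples; "
                         "consider relaxing the coverage thresholds")
    common = common.sortlevel([0, 1])[0]
    sites = common.to_frame(index=False)
    meth = np.column_stack([filtered[sid].loc[common, "meth"].to_numpy()
                            for sid in samples.sample_id])
    total = np.column_stack([filtered[sid].loc[common, "total"].to_numpy()
                             for sid in samples.sample_id])
    return MethylationMatrix(sites=sites, meth=meth, total=total, samples=samples)


def relaxed_background(sample_sites: dict[str, pd.DataFrame],
                       min_coverage: int = 3, min_samples: int = 1) -> pd.DataFrame:
    """Union of sites with total >= min_coverage in >= min_samples samples.

    This is the genome-wide background used for distribution summaries, not
    for testing.
    """
    counts: pd.Series | None = None
    for df in sample_sites.values():
        ok = df[df.total >= min_coverage].set_index(["chrom", "pos"])
        s = pd.Series(1, index=ok.index)
        counts = s if counts is None else counts.add(s, fill_value=0)
    if counts is None or counts.empty:
        return pd.DataFrame(columns=["chrom", "pos"])
    keep = counts[counts >= min_samples].index.sortlevel([0, 1])[0]
    return keep.to_frame(index=False).reset_index(drop=True)
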