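"""Configuration objects for simulation and pipeline runs.

Both configs are plain dataclasses that round-trip losslessly through YAML so a
run can be reproduced from its recorded configuration file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-habitat RRBS + expression dataset.

    Defaults emulate the study design the analysis targets: 12 birds (6 urban,
    6 forest), a mostly hypomethylated CpG landscape (marginal site methylation
    Beta(0.5, 2.4), median ~= 0.10), per-CpG-unit read coverage negative
    binomial with mean ~30x, and a planted set of sites whose between-habitat
    methylation shift exceeds 25 percentage points, some clustered within 2 kb.
    """

    n_per_group: int = 6
    n_chromosomes: int = 1
    chrom_length_bp: int = 500_000

    # background sequence composition (CpG-suppressed, GC ~40%)
    n_cgi: int = 8
    cgi_length_bp: int = 800

    # site methylation baseline: Beta(a, b) with median ~0.10
    beta_a: float = 0.5
    beta_b: float = 2.4

    # read coverage per CpG unit (both strands pooled): NB(mean, dispersion)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 16.0

    # planted differential methylation
    n_true_dms: int = 60
    true_effect: float = 0.35  # additive shift on the proportion scale
    dmr_fraction: float = 0.5  # fraction of true DMSs planted in >=3-site 2 kb clusters
    hyper_fraction: float = 0.75  # P(planted site is hypermethylated in urban)

    # genes and expression
    n_genes: int = 60
    n_tss_dms: int = 15  # planted singleton DMSs placed inside gene TSS windows
    expression_tss_slope: float = -0.03  # log2 expression per methylation percentage point
    nonexpressed_fraction: float = 0.2
    expression_log2_mean_range: tuple[float, float] = (4.0, 10.0)
    expression_dispersion: float = 20.0

    rng_seed: int = 0

    def validate(self) -> None:
        positive = [
            self.n_per_group, self.n_chromosomes, self.chrom_length_bp,
            self.cgi_length_bp, self.coverage_mean, self.coverage_dispersion,
            self.n_genes, self.expression_dispersion,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all size/rate parameters must be positive")
        if self.chrom_length_bp < 10_000:
            raise ValueError("chrom_length_bp must be at least 10 kb")
        if not (0.25 < self.true_effect <= 0.75):
            raise ValueError("true_effect must lie in (0.25, 0.75]")
        if self.n_cgi < 0 or self.n_true_dms < 0 or self.n_tss_dms < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.dmr_fraction <= 1.0):
            raise ValueError("dmr_fraction must lie in [0, 1]")
        if not (0.0 <= self.nonexpressed_fraction <= 1.0):
            raise ValueError("nonexpressed_fraction must lie in [0, 1]")
        if self.n_tss_dms > self.n_true_dms:
            raise ValueError("n_tss_dms cannot exceed n_true_dms")


@dataclass
class RunConfig:
    """All thresholds of the end-to-end pipeline, in one place.

    The defaults are the analysis constants: >=10x coverage with a per-sample
    99.9th-percentile cap, sites covered in all samples, |difference| > 25
    percentage points with q < 0.01 (SLIM-adjusted), DMRs as >=3 DMSs within
    2 kb, promoters 3 kb upstream (excluding the TSS window -300/+50), 2 kb
    CGI shores, expressed genes as count >= 10 in >= 25% of individuals, GO
    FDR 0.05, and a 1,000-iteration label permutation test.
    """

    outdir: str = "urbmeth_run"
    min_coverage: int = 10
    max_quantile: float = 0.999
    relaxed_min_coverage: int = 3
    relaxed_min_samples: int = 1
    diff_threshold: float = 25.0
    q_threshold: float = 0.01
    dmr_window: int = 2000
    dmr_min_sites: int = 3
    promoter_bp: int = 3000
    tss_upstream: int = 300
    tss_downstream: int = 50
    shore_bp: int = 2000
    cgi_window: int = 100
    cgi_n_windows_avg: int = 10
    cgi_min_len: int = 200
    cgi_gc_min: float = 0.50
    cgi_obs_exp_min: float = 0.60
    expressed_min_count: int = 10
    expressed_min_fraction: float = 0.25
    go_fdr: float = 0.05
    perm_n_iter: int = 1000
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if min(self.min_coverage, self.dmr_window, self.dmr_min_sites,
               self.promoter_bp, self.shore_bp, self.cgi_window,
               self.cgi_min_len, self.expressed_min_count, self.perm_n_iter) <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.max_quantile <= 1):
            raise ValueError("max_quantile must lie in (0, 1]")
        self.simulation.validate()


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return list(x)
        return x

    return conv(d)


def save_config(cfg: SimulationConfig | RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_simulation_config(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if "expression_log2_mean_range" in d:
        d["expression_log2_mean_range"] = tuple(d["expression_log2_mean_range"])
    return SimulationConfig(**d)


def load_run_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    sim = d.pop("simulation", None)
    cfg = RunConfig(**d)
    if sim is not None:
        if "expression_log2_mean_range" in sim:
            sim["expression_log2_mean_range"] = tuple(sim["expression_log2_mean_range"])
        cfg.simulation = SimulationConfig(**sim)
    return cfg
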