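"""Pipeline configuration and end-to-end orchestration.

One YAML document holds every stage's tunables — the inclusion rule
(20× coverage in ≥7 of 10 populations), the differential gates (alpha
0.05, |Δ| > 0.20, BH correction), the specificity rule (|z| > 1.65 in all
replicates, ≥0.10 gap to the next population), the 40-base cluster window,
the 100-base locus gap, the 2% ordering noise floor, and the generator
settings. Unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .differential import pairwise_differential, population_summary


@dataclass
class SimulateConfig:
    n_sites: int = 200
    n_populations: int = 10
    replicates_per_pop: int = 3
    mean_depth: float = 200.0
    depth_dispersion: float = 0.1
    overdispersion: float = 0.01
    snp_rate: float = 0.05
    conversion_noise_rate: float = 0.05
    n_specific: int = 20
    specific_shift_min: float = 0.15
    specific_shift_max: float = 0.40


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    # inclusion
    min_coverage: int = 20
    min_populations: int = 7
    reproducibility_max_spread: float = 0.2
    # differential
    alpha: float = 0.05
    min_delta: float = 0.20
    correction: str = "bh"
    # specificity
    z_thresh: float = 1.65
    min_gap: float = 0.10
    # linkage / discovery geometry
    cluster_window: int = 40
    locus_gap: int = 100
    noise_floor: float = 0.02

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("simulate", {})
        sim_allowed = {f.name for f in dataclasses.fields(SimulateConfig)}
        sim_unknown = set(sim_raw) - sim_allowed
        if sim_unknown:
            raise ValueError(f"unknown simulate keys: {sorted(sim_unknown)}")
        return cls(simulate=SimulateConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Simulate → quantify → differential → specificity → linkage.

    Writes every stage's table to ``outdir`` plus a provenance record
    (package version, config hash, stage timings). Deterministic under
    config.seed: a rerun writes identical tables.
    """
    from .linkage import find_clusters
    from .quantify import InclusionRule, apply_inclusion, levels_frame
    from .specificity import call_specific
    from .synthetic import gen_counts, make_truth, truth_report

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    sim = config.simulate
    shifts = None
    if sim.n_specific > 0:
        import numpy as np

        shifts = list(
            np.linspace(sim.specific_shift_min, sim.specific_shift_max, sim.n_specific)
        )
    truth = make_truth(
        n_sites=sim.n_sites,
        n_populations=sim.n_populations,
        replicates_per_pop=sim.replicates_per_pop,
        mean_depth=sim.mean_depth,
        depth_dispersion=sim.depth_dispersion,
        overdispersion=sim.overdispersion,
        snp_rate=sim.snp_rate,
        conversion_noise_rate=sim.conversion_noise_rate,
        shift_values=shifts,
        seed=config.seed,
    )
    counts, sheet = gen_counts(truth)
    counts.write(outdir / "counts.tsv")
    sheet.write(outdir / "samples.tsv")
    truth_report(truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    edit_sites = truth.edit_sites()
    edit_counts = counts.select_sites(edit_sites)
    rule = InclusionRule(
        min_coverage=config.min_coverage,
        min_populations=config.min_populations,
        total_populations=sim.n_populations,
        reproducibility_max_spread=config.reproducibility_max_spread,
    )
    kept, qc = apply_inclusion(edit_counts, sheet, rule)
    levels_frame(edit_counts, sheet).to_csv(outdir / "levels.tsv", sep="\t", index=False)
    qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    timings["quantify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pairwise = pairwise_differential(
        edit_counts,
        sheet,
        sites=kept,
        alpha=config.alpha,
        min_delta=config.min_delta,
        correction=config.correction,
        min_coverage=config.min_coverage,
    )
    pairwise.to_csv(outdir / "pairwise.tsv", sep="\t", index=False)
    summary, bins = population_summary(pairwise)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    bins.to_csv(outdir / "summary_bins.tsv", sep="\t", index=False)
    timings["differential"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    specific = call_specific(
        edit_counts,
        sheet,
        sites=kept,
        z_thresh=config.z_thresh,
        min_gap=config.min_gap,
    )
    specific.to_csv(outdir / "specific.tsv", sep="\t", index=False)
    timings["specificity"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    from .io_model import SiteKey

    spec_sites = [
        SiteKey(r["chrom"], int(r["pos"]), r["strand"]) for _, r in specific.iterrows()
    ]
    clusters = find_clusters(spec_sites, cluster_window=config.cluster_window)
    cluster_rows = []
    for ci, cl in enumerate(clusters):
        for s in cl.sites:
            cluster_rows.append(
                {"cluster": ci, "chrom": s.chrom, "pos": s.pos, "strand": s.strand}
            )
    pd.DataFrame(
        cluster_rows, columns=["cluster", "chrom", "pos", "strand"]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    timings["linkage"] = time.perf_counter() - t0

    from . import __version__ as pkg_version

    provenance = {
        "package": "editscape",
        "version": pkg_version,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "n_sites_kept": len(kept),
        "n_differential": int(pairwise["significant"].sum()) if not pairwise.empty else 0,
        "n_specific_calls": len(specific),
        "n_clusters": len(clusters),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return provenance
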