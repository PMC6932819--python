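"""Config-driven simulation scenarios: SQUICH vs SRS at matched depths.

Four preset regimes are provided, mirroring the study conditions used
throughout the package:

``simulation1``  needle in a haystack — one species at 10**15 molecules and
                 20 needles at 100; detection power vs depth.
``simulation2``  2-fold enrichment of 20 species over a background of
                 262,124 species at level 100 (the full 2**18 CGA codebook
                 with cross-hybridization); enrichment calling.
``simulation3``  dynamic range — 10 species at each abundance x*10**y
                 (x=1..10, y=0..9) plus 3000 background species at 100;
                 quantification, dropout and log MSE.
``single_cell``  one pseudo-cell with ~4000 expressed transcripts over five
                 decades.

Each replicate runs the stochastic protocol, sequences the coded pool at the
requested depths, applies the scenario's estimator, and scores against
ground truth; the SRS arm samples the original population with replacement
at its own depth grid.  (config, seed) determines every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import populations as pops
from .chemistry import ChemistryParams
from .codes import enumerate_cga
from .estimators import call_enriched, sem_point, srs_point
from .metrics import score
from .protocol import ProbeSchedule, run_protocol, sequence_pool, srs_sample

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "compare_squich_srs",
    "simulation1",
    "simulation2",
    "simulation3",
    "single_cell",
    "load_config",
    "PRESETS",
]


@dataclass
class ScenarioConfig:
    name: str
    population: pops.SpeciesPopulation
    schedule: ProbeSchedule
    chemistry: ChemistryParams
    depths: tuple[int, ...]
    srs_depths: tuple[int, ...]
    replicates: int
    seed: int = 0
    estimator: str = "sem"  # "sem" or "enrichment"
    mode: str = "stochastic"
    tau_reads: int = 1
    alpha: float = 0.05
    #: success rule used by compare_squich_srs: "recall" (full recall of the
    #: marked species), "recall_no_fp" (that plus zero false positives), or
    #: "dropout<=N".
    success: str = "recall"
    spec: dict = field(default_factory=dict, repr=False)

    def manifest(self) -> dict:
        blob = json.dumps(self.spec, sort_keys=True, default=str)
        return {
            "scenario": self.name,
            "seed": self.seed,
            "replicates": self.replicates,
            "config": self.spec,
            "config_sha1": hashlib.sha1(blob.encode()).hexdigest(),
        }


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    per_replicate: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        num = ["recall", "fp_count", "dropout_count", "log_mse", "pearson", "spearman", "success"]
        present = [c for c in num if c in self.per_replicate.columns]
        return (
            self.per_replicate.groupby(["method", "depth"])[present]
            .agg(["mean", "min", "max"])
            .reset_index()
        )

    def manifest(self) -> dict:
        return self.config.manifest()


def _success(cfg: ScenarioConfig, report) -> bool:
    rule = cfg.success
    if rule == "recall":
        return report.recall == 1.0
    if rule == "recall_no_fp":
        return report.recall == 1.0 and (report.fp_count or 0) == 0
    if rule.startswith("dropout<="):
        return report.dropout_count <= int(rule.split("<=")[1])
    raise ValueError(f"unknown success rule {rule!r}")


def run_scenario(
    cfg: ScenarioConfig,
    replicates: int | None = None,
    seed: int | None = None,
) -> ScenarioResult:
    """Run all replicates and depths of a scenario; returns per-replicate rows."""
    reps = cfg.replicates if replicates is None else replicates
    master = cfg.seed if seed is None else seed
    pop = cfg.population
    positives = pop.marked_ids if pop.marked_ids.size else None
    streams = np.random.SeedSequence(master).spawn(reps)
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(streams[rep])
        pool = run_protocol(pop, cfg.schedule, cfg.chemistry, mode=cfg.mode, rng=rng)
        for depth in cfg.depths:
            matrix = sequence_pool(pool, depth, rng)
            if cfg.estimator == "enrichment":
                call = call_enriched(matrix, cfg.schedule, alpha=cfg.alpha)
                est = sem_point(matrix, cfg.schedule, tau_reads=cfg.tau_reads)
                report = score(est, pop, positives=positives, called=call.called)
            else:
                est = sem_point(matrix, cfg.schedule, tau_reads=cfg.tau_reads)
                report = score(est, pop, positives=positives)
            rows.append(_row(cfg, "squich", depth, rep, report))
        for depth in cfg.srs_depths:
            counts = srs_sample(pop, depth, rng)
            est = srs_point(counts)
            if cfg.estimator == "enrichment":
                called = _srs_enrichment_call(counts, cfg.alpha)
                report = score(est, pop, positives=positives, called=called)
            else:
                report = score(est, pop, positives=positives)
            rows.append(_row(cfg, "srs", depth, rep, report))
    return ScenarioResult(config=cfg, per_replicate=pd.DataFrame(rows))


def _row(cfg, method, depth, rep, report) -> dict:
    return {
        "scenario": cfg.name,
        "method": method,
        "depth": depth,
        "replicate": rep,
        "recall": report.recall,
        "fp_count": report.fp_count,
        "dropout_count": report.dropout_count,
        "dropout_rate": report.dropout_rate,
        "log_mse": report.log_mse,
        "pearson": report.pearson,
        "spearman": report.spearman,
        "success": _success(cfg, report),
    }


def _srs_enrichment_call(counts: np.ndarray, alpha: float) -> np.ndarray:
    """Enrichment calls from raw SRS counts.

    Same Poisson-tail/Bonferroni logic as the round-stratified caller, with
    the total count as the evidence statistic: the null mean is the
    upper-quartile mean of counts (which upper-bounds the background mean),
    and the threshold controls the family-wise error over all species.
    """
    from scipy import stats

    counts = np.asarray(counts, dtype=np.int64)
    S = counts.size
    k_top = max(1, S // 4)
    mu = float(np.partition(counts, S - k_top)[S - k_top:].mean())
    if mu <= 0:
        tau = 1
    else:
        tau = int(stats.poisson.isf(alpha / S, mu)) + 1
        while tau > 1 and S * stats.poisson.sf(tau - 2, mu) <= alpha:
            tau -= 1
    return np.flatnonzero(counts >= tau)


def compare_squich_srs(
    result: ScenarioResult | None = None,
    cfg: ScenarioConfig | None = None,
    **run_kwargs,
) -> dict:
    """Smallest tested depth at which each method meets the success rule.

    Success must hold in every replicate.  Returns the two depths and their
    ratio; a criterion never met is reported as None with the max tested
    depth noted.
    """
    if result is None:
        if cfg is None:
            raise ValueError("need a ScenarioResult or a ScenarioConfig")
        result = run_scenario(cfg, **run_kwargs)
    df = result.per_replicate
    out = {"scenario": result.config.name}
    for method in ("squich", "srs"):
        sub = df[df.method == method]
        depths = sorted(sub.depth.unique())
        if len(depths) < 2:
            raise ValueError(f"need >= 2 tested depths for {method}")
        ok = [d for d in depths if bool(sub[sub.depth == d].success.all())]
        out[f"{method}_depth"] = min(ok) if ok else None
        out[f"{method}_max_tested"] = max(depths)
    if out["squich_depth"] and out["srs_depth"]:
        out["depth_ratio"] = out["srs_depth"] / out["squich_depth"]
    else:
        out["depth_ratio"] = None
    return out


# ---------------------------------------------------------------------------
# Presets


def simulation1(
    replicates: int = 1000,
    background_abundance: int = 10**15,
    depths: Sequence[int] = (10**3, 10**4, 10**5),
    srs_depths: Sequence[int] = (10**3, 10**4, 10**5),
    seed: int = 0,
) -> ScenarioConfig:
    """Needle in a haystack: 20 needles at 100 against one giant species.

    The 16-round decade schedule brackets abundances up to beyond 10**15.
    """
    pop = pops.build_needle_haystack(background_abundance, 20, 100)
    sched = ProbeSchedule.geometric(rounds=16, encoder=10, growth=10)
    return ScenarioConfig(
        name="simulation1",
        population=pop,
        schedule=sched,
        chemistry=ChemistryParams(),
        depths=tuple(int(d) for d in depths),
        srs_depths=tuple(int(d) for d in srs_depths),
        replicates=replicates,
        seed=seed,
        estimator="sem",
        success="recall",
        spec={
            "preset": "simulation1",
            "background_abundance": background_abundance,
            "depths": list(map(int, depths)),
            "srs_depths": list(map(int, srs_depths)),
        },
    )


def simulation2(
    replicates: int = 100,
    depths: Sequence[int] = (10**5,),
    srs_depths: Sequence[int] = (10**5,),
    codebook_order: int = 18,
    seed: int = 0,
) -> ScenarioConfig:
    """2-fold enrichment of 20 species in a 2**18-species background.

    Competitor-only early rounds exhaust the background level (100) before
    the encoder-only final round, so only enriched species (200) still have
    molecules to tag when encoders appear; cross-hybridization runs over the
    full CGA neighbor structure.  The tapering competitor amounts (100, 20,
    5) carry a margin above the background level so that the stochastic
    carry-over tail of unreacted background molecules is also exhausted
    before encoders are introduced.
    """
    cb = enumerate_cga(codebook_order)
    pop = pops.build_fold_change(cb.size, 100, 20, 2.0)
    sched = ProbeSchedule.from_amounts(E=[0, 0, 0, 100], C=[100, 20, 5, 0])
    chem = ChemistryParams(neighbor_map=cb.neighbor_csr())
    return ScenarioConfig(
        name="simulation2",
        population=pop,
        schedule=sched,
        chemistry=chem,
        depths=tuple(int(d) for d in depths),
        srs_depths=tuple(int(d) for d in srs_depths),
        replicates=replicates,
        seed=seed,
        estimator="enrichment",
        success="recall_no_fp",
        spec={
            "preset": "simulation2",
            "codebook_order": codebook_order,
            "depths": list(map(int, depths)),
            "srs_depths": list(map(int, srs_depths)),
        },
    )


def simulation3(
    replicates: int = 100,
    depths: Sequence[int] = (10**5,),
    srs_depths: Sequence[int] = (10**5,),
    background_count: int = 3000,
    seed: int = 0,
) -> ScenarioConfig:
    """Dynamic range: abundances x*10**y over ten decades plus background."""
    pop = pops.build_dynamic_range(background_count=background_count)
    sched = ProbeSchedule.geometric(rounds=16, encoder=10, growth=10)
    return ScenarioConfig(
        name="simulation3",
        population=pop,
        schedule=sched,
        chemistry=ChemistryParams(),
        depths=tuple(int(d) for d in depths),
        srs_depths=tuple(int(d) for d in srs_depths),
        replicates=replicates,
        seed=seed,
        estimator="sem",
        success="recall",
        spec={
            "preset": "simulation3",
            "background_count": background_count,
            "depths": list(map(int, depths)),
            "srs_depths": list(map(int, srs_depths)),
        },
    )


def single_cell(
    replicates: int = 100,
    depths: Sequence[int] = (10**5,),
    srs_depths: Sequence[int] = (10**5,),
    seed: int = 0,
) -> ScenarioConfig:
    """One pseudo-cell: ~4000 transcripts over five decades of expression."""
    pop = pops.build_single_cell()
    sched = ProbeSchedule.geometric(rounds=8, encoder=10, growth=10)
    return ScenarioConfig(
        name="single_cell",
        population=pop,
        schedule=sched,
        chemistry=ChemistryParams(),
        depths=tuple(int(d) for d in depths),
        srs_depths=tuple(int(d) for d in srs_depths),
        replicates=replicates,
        seed=seed,
        estimator="sem",
        success="recall",
        spec={
            "preset": "single_cell",
            "depths": list(map(int, depths)),
            "srs_depths": list(map(int, srs_depths)),
        },
    )


PRESETS: dict[str, Callable[..., ScenarioConfig]] = {
    "simulation1": simulation1,
    "simulation2": simulation2,
    "simulation3": simulation3,
    "single_cell": single_cell,
}

_BUILDERS = {
    "needle_haystack": pops.build_needle_haystack,
    "fold_change": pops.build_fold_change,
    "dynamic_range": pops.build_dynamic_range,
    "single_cell": pops.build_single_cell,
}


def load_config(path) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML file.

    Two forms are accepted.  Preset form::

        preset: simulation1
        replicates: 100
        seed: 7

    Explicit form::

        name: my_scenario
        population: {builder: dynamic_range, args: {background_count: 3000}}
        schedule: {geometric: {rounds: 16, encoder: 10, growth: 10}}
        chemistry: {eta: 0.95, eps: 0.01, neighbors: null}   # or cga:<n>
        depths: [100000]
        srs_depths: [100000]
        replicates: 100
        seed: 0
        estimator: sem
        success: recall
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    if "preset" in raw:
        preset = raw.pop("preset")
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        return PRESETS[preset](**raw)

    missing = {"name", "population", "schedule", "depths", "replicates"} - raw.keys()
    if missing:
        raise ValueError(f"config missing keys: {sorted(missing)}")
    pop_block = raw["population"]
    if "abundances" in pop_block:
        pop = pops.SpeciesPopulation(np.asarray(pop_block["abundances"], dtype=np.int64))
    else:
        builder = _BUILDERS.get(pop_block.get("builder"))
        if builder is None:
            raise ValueError(f"unknown population builder {pop_block.get('builder')!r}")
        pop = builder(**pop_block.get("args", {}))
    sch_block = raw["schedule"]
    if "geometric" in sch_block:
        sched = ProbeSchedule.geometric(**sch_block["geometric"])
    else:
        sched = ProbeSchedule.from_amounts(E=sch_block["E"], C=sch_block["C"])
    chem_block = dict(raw.get("chemistry", {}))
    neighbors = chem_block.pop("neighbors", None)
    if isinstance(neighbors, str) and neighbors.startswith("cga:"):
        neighbors = enumerate_cga(int(neighbors.split(":")[1])).neighbor_csr()
    chem = ChemistryParams(neighbor_map=neighbors, **chem_block)
    return ScenarioConfig(
        name=raw["name"],
        population=pop,
        schedule=sched,
        chemistry=chem,
        depths=tuple(int(d) for d in raw["depths"]),
        srs_depths=tuple(int(d) for d in raw.get("srs_depths", raw["depths"])),
        replicates=int(raw["replicates"]),
        seed=int(raw.get("seed", 0)),
        estimator=raw.get("estimator", "sem"),
        tau_reads=int(raw.get("tau_reads", 1)),
        alpha=float(raw.get("alpha", 0.05)),
        success=raw.get("success", "recall"),
        spec=raw,
    )
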