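"""Experiment orchestration: generations, runs, persistence, replication.

Each generation, 16 of the 48 population members are realized as phenotypes
and presented in four 4-stimulus trials; gaze is simulated (or ingested),
fixations are filtered and scored, the remaining 32 members get interpolated
fitness, and generational replacement produces the next population. A
participant is two independent evolutionary runs (interleaved or blocked)
with disjoint RNG substreams derived from one master seed, so results are
bit-for-bit reproducible.
"""

from __future__ import annotations

import copy
import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import genome
from .genome import (
    GeneticParams,
    Individual,
    InvalidConfigError,
    Population,
    init_population,
    next_generation,
)
from .observer import ObserverPolicy, simulate_trial_gaze
from .oculometrics import (
    AoiMetrics,
    FitnessWeights,
    assign_aoi,
    detect_fixations_idt,
    estimate_fitness,
    score_trial,
)
from .stimulus import layout_trial, realize_phenotype

__all__ = [
    "ExperimentConfig",
    "GenerationRecord",
    "RunResult",
    "RunRngs",
    "ConfigError",
    "LoadError",
    "rng_bundle",
    "select_presented",
    "run_generation",
    "run_experiment",
    "save_results",
    "load_results",
    "replicate_condition",
    "CONDITIONS",
]


class ConfigError(ValueError):
    """Invalid experiment configuration; the message lists every violation."""


class LoadError(IOError):
    """A saved result set is incomplete or malformed."""


@dataclass
class ExperimentConfig:
    population_size: int = 48
    presented_per_generation: int = 16
    stimuli_per_trial: int = 4
    generations: int = 20
    runs_per_participant: int = 2
    run_arrangement: str = "blocked"  # or "interleaved"
    trial_duration_ms: float = 5000.0
    idt_radius_deg: float = 0.5
    idt_min_duration_ms: float = 100.0
    control_fitness_mode: str = "uniform"  # control runs: i.i.d. U(0,1) fitness
    estimation_method: str = "shepard"
    policy: ObserverPolicy = field(default_factory=ObserverPolicy)
    genetic: GeneticParams = field(default_factory=GeneticParams)
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    master_seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.population_size < 4:
            problems.append("population_size must be >= 4")
        if self.presented_per_generation > self.population_size:
            problems.append("presented_per_generation must be <= population_size")
        if self.presented_per_generation % self.stimuli_per_trial != 0:
            problems.append(
                "presented_per_generation must be divisible by stimuli_per_trial"
            )
        if self.stimuli_per_trial != 4:
            problems.append("stimuli_per_trial must be 4 (one disk per screen quadrant)")
        if self.generations < 1:
            problems.append("generations must be >= 1")
        if self.runs_per_participant < 1:
            problems.append("runs_per_participant must be >= 1")
        if self.run_arrangement not in ("interleaved", "blocked"):
            problems.append("run_arrangement must be 'interleaved' or 'blocked'")
        if self.trial_duration_ms <= 0:
            problems.append("trial_duration_ms must be > 0")
        if self.control_fitness_mode not in ("uniform", "zero"):
            problems.append("control_fitness_mode must be 'uniform' or 'zero'")
        try:
            self.genetic.validate(self.population_size)
        except InvalidConfigError as exc:
            problems.append(str(exc))
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("policy"), dict):
            d["policy"] = ObserverPolicy(**d["policy"])
        if isinstance(d.get("genetic"), dict):
            d["genetic"] = GeneticParams(**d["genetic"])
        if isinstance(d.get("weights"), dict):
            d["weights"] = FitnessWeights(**d["weights"])
        return cls(**d)


@dataclass
class GenerationRecord:
    """Snapshot of one scored generation, the unit of all downstream analysis."""

    generation_index: int
    members: list[Individual]  # scored population, pre-replacement
    presented_trials: list[list[int]]  # member indices per trial
    trial_metrics: list[AoiMetrics]


@dataclass
class RunResult:
    run_index: int
    records: list[GenerationRecord]
    config: dict
    master_seed: int


@dataclass
class RunRngs:
    """Named RNG substreams so modules stay independently testable."""

    init: np.random.Generator
    stimulus: np.random.Generator
    gaze: np.random.Generator
    genetics: np.random.Generator


def rng_bundle(master_seed: int, run_index: int) -> RunRngs:
    """Disjoint substreams for one run, derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(run_index,))
    children = ss.spawn(4)
    return RunRngs(*(np.random.default_rng(c) for c in children))


def select_presented(
    pop: Population, cfg: ExperimentConfig, rng: np.random.Generator
) -> list[list[int]]:
    """Uniformly sample the presented subset and partition it into trials."""
    idx = rng.choice(
        len(pop.members), size=cfg.presented_per_generation, replace=False
    )
    k = cfg.stimuli_per_trial
    return [list(map(int, idx[i : i + k])) for i in range(0, len(idx), k)]


def run_generation(
    pop: Population, cfg: ExperimentConfig, rngs: RunRngs
) -> tuple[GenerationRecord, Population]:
    """Score one generation (by gaze or control rule) and breed the next."""
    if cfg.policy.kind == "none":
        for m in pop.members:
            m.fitness = (
                float(rngs.gaze.uniform()) if cfg.control_fitness_mode == "uniform" else 0.0
            )
            m.provenance = genome.ESTIMATED
        trials: list[list[int]] = []
        metrics: list[AoiMetrics] = []
    else:
        trials = select_presented(pop, cfg, rngs.genetics)
        metrics = []
        for trial in trials:
            patterns = [
                realize_phenotype(pop.members[i].chromosome, rngs.stimulus)
                for i in trial
            ]
            layout = layout_trial(patterns, rngs.stimulus)
            stream = simulate_trial_gaze(
                layout, cfg.policy, rngs.gaze, cfg.trial_duration_ms
            )
            fixations = detect_fixations_idt(
                stream, cfg.idt_radius_deg, cfg.idt_min_duration_ms
            )
            m = assign_aoi(fixations, layout)
            metrics.append(m)
            for i, score in zip(trial, score_trial(m, cfg.weights)):
                pop.members[i].fitness = score
                pop.members[i].provenance = genome.PRESENTED
        presented_idx = {i for trial in trials for i in trial}
        unpresented_idx = [
            i for i in range(len(pop.members)) if i not in presented_idx
        ]
        anchors = [
            (pop.members[i].chromosome, pop.members[i].fitness)
            for i in sorted(presented_idx)
        ]
        estimates = estimate_fitness(
            anchors,
            [pop.members[i].chromosome for i in unpresented_idx],
            method=cfg.estimation_method,
        )
        for i, est in zip(unpresented_idx, estimates):
            pop.members[i].fitness = est
            pop.members[i].provenance = genome.ESTIMATED
    record = GenerationRecord(
        generation_index=pop.generation_index,
        members=copy.deepcopy(pop.members),
        presented_trials=trials,
        trial_metrics=metrics,
    )
    new_pop = next_generation(pop, cfg.genetic, rngs.genetics)
    return record, new_pop


def run_experiment(cfg: ExperimentConfig, log=None) -> list[RunResult]:
    """Execute all runs of one participant's experiment.

    Runs use disjoint RNG substreams, so interleaved and blocked arrangements
    produce identical per-run results and an identical master seed reproduces
    everything bit-for-bit.
    """
    cfg.validate()
    n_runs = cfg.runs_per_participant
    rngs = [rng_bundle(cfg.master_seed, r) for r in range(n_runs)]
    pops = [init_population(rngs[r].init, cfg.population_size) for r in range(n_runs)]
    records: list[list[GenerationRecord]] = [[] for _ in range(n_runs)]

    def step(r: int) -> None:
        rec, pops[r] = run_generation(pops[r], cfg, rngs[r])
        records[r].append(rec)
        if log is not None:
            print(
                f"run {r + 1}/{n_runs} generation {rec.generation_index}/{cfg.generations}",
                file=log,
            )

    if cfg.run_arrangement == "interleaved":
        for _ in range(cfg.generations):
            for r in range(n_runs):
                step(r)
    else:
        for r in range(n_runs):
            for _ in range(cfg.generations):
                step(r)
    return [
        RunResult(
            run_index=r,
            records=records[r],
            config=cfg.to_dict(),
            master_seed=cfg.master_seed,
        )
        for r in range(n_runs)
    ]


# ---------------------------------------------------------------------------
# persistence: JSON manifest + one CSV population snapshot per generation

_CSV_FIELDS = ["generation", "index", "ds", "ori", "bina", "fitness", "provenance"]


def _write_generation_csv(path: Path, rec: GenerationRecord) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for i, m in enumerate(rec.members):
            writer.writerow(
                [
                    rec.generation_index,
                    i,
                    repr(m.chromosome.ds),
                    repr(m.chromosome.ori),
                    m.chromosome.bina,
                    "" if m.fitness is None else repr(m.fitness),
                    m.provenance,
                ]
            )


def _read_generation_csv(path: Path) -> tuple[int, list[Individual]]:
    members = []
    gen = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            gen = int(row["generation"])
            members.append(
                Individual(
                    chromosome=genome.Chromosome(
                        ds=float(row["ds"]),
                        ori=float(row["ori"]),
                        bina=int(row["bina"]),
                    ),
                    fitness=None if row["fitness"] == "" else float(row["fitness"]),
                    provenance=row["provenance"],
                )
            )
    if gen is None:
        raise LoadError(f"{path}: empty population snapshot")
    return gen, members


def save_results(results: list[RunResult], path) -> None:
    """Write runs to ``path/``: manifest.json plus per-generation CSV snapshots."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"format": "gdea-results-v1", "runs": []}
    for res in results:
        run_entry = {
            "run_index": res.run_index,
            "master_seed": res.master_seed,
            "config": res.config,
            "generations": [],
        }
        for rec in res.records:
            fname = f"run{res.run_index}_gen{rec.generation_index:02d}.csv"
            _write_generation_csv(out / fname, rec)
            run_entry["generations"].append(
                {
                    "generation_index": rec.generation_index,
                    "file": fname,
                    "presented_trials": rec.presented_trials,
                    "trial_metrics": [
                        {
                            "dwell_ms": m.dwell_ms,
                            "first_fix_rank": m.first_fix_rank,
                            "revisits": m.revisits,
                        }
                        for m in rec.trial_metrics
                    ],
                }
            )
        manifest["runs"].append(run_entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_results(path) -> list[RunResult]:
    """Inverse of :func:`save_results`; ``load(save(x)) == x``."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise LoadError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    results = []
    for run_entry in manifest["runs"]:
        records = []
        for gen_entry in run_entry["generations"]:
            csv_path = root / gen_entry["file"]
            if not csv_path.exists():
                raise LoadError(f"manifest references missing file: {csv_path}")
            gen, members = _read_generation_csv(csv_path)
            if gen != gen_entry["generation_index"]:
                raise LoadError(
                    f"{csv_path}: generation {gen} != manifest "
                    f"{gen_entry['generation_index']}"
                )
            records.append(
                GenerationRecord(
                    generation_index=gen,
                    members=members,
                    presented_trials=[
                        list(t) for t in gen_entry["presented_trials"]
                    ],
                    trial_metrics=[
                        AoiMetrics(
                            dwell_ms=m["dwell_ms"],
                            first_fix_rank=m["first_fix_rank"],
                            revisits=m["revisits"],
                        )
                        for m in gen_entry["trial_metrics"]
                    ],
                )
            )
        results.append(
            RunResult(
                run_index=run_entry["run_index"],
                records=records,
                config=run_entry["config"],
                master_seed=run_entry["master_seed"],
            )
        )
    return results


# ---------------------------------------------------------------------------
# condition-level replication

#: instruction conditions mapped to observer policies; ``strict`` is the
#: preference mechanism with zero tolerance, used for sensitivity contrasts
CONDITIONS = {
    "symmetry": dict(kind="symmetry"),
    "preference": dict(kind="preference", tolerance=0.5),
    "strict": dict(kind="preference", tolerance=0.0),
    "freeview": dict(kind="freeview"),
    "control": dict(kind="none"),
}


def participant_seed(master_seed: int, participant: int) -> int:
    """A stable sub-seed (< 2**31) for one simulated participant."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(participant,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def replicate_condition(
    condition: str,
    participants: int = 18,
    master_seed: int = 0,
    config: ExperimentConfig | None = None,
    log=None,
) -> list[list[RunResult]]:
    """Simulate one instruction condition: ``participants`` independent
    two-run experiments under the condition's observer policy.

    Returns one list of RunResults per participant. Participants under
    different conditions but the same ``master_seed`` and index share their
    sub-seed, enabling matched-seed paired comparisons.
    """
    if condition not in CONDITIONS:
        raise ConfigError(
            f"unknown condition {condition!r}; choose from {sorted(CONDITIONS)}"
        )
    base = config if config is not None else ExperimentConfig()
    out = []
    for p in range(participants):
        cfg = copy.deepcopy(base)
        cfg.policy = ObserverPolicy(
            **{**dataclasses.asdict(base.policy), **CONDITIONS[condition]}
        )
        cfg.master_seed = participant_seed(master_seed, p)
        if log is not None:
            print(f"[{condition}] participant {p + 1}/{participants}", file=log)
        out.append(run_experiment(cfg))
    return out
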