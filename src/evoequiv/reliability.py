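"""Semantic non-equivalence analysis of champion programs.

Champion wall-followers that behave identically *inside* the labyrinth
(all perfect) need not compute the same boolean function: compared on
every one of the 4,096 possible sensor/move states, independently
evolved champions typically disagree on a substantial fraction — which
is exactly why their behaviour outside the training labyrinth is
unpredictable.  This module computes the pairwise disagreement matrix
over a set of programs (including the three packaged published
champions) and orchestrates the full two-experiment pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .logic_expr import (BoolExpr, N_STATES, truth_vector,
                         disagreement_count, serialize)
from .gridworld import GridWorld, program_controller, is_perfect, run_journey
from . import gp_engine, neuroevolution, fixtures

__all__ = [
    "ReliabilityReport",
    "PipelineConfig",
    "disagreement_matrix",
    "behavioral_divergence",
    "run_full_pipeline",
]


@dataclass
class ReliabilityReport:
    """Pairwise truth-table disagreements among named programs."""

    ids: list[str]
    matrix: np.ndarray                      # (k, k) ints in [0, 4096]
    perfect: dict[str, bool] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=int)
        k = len(self.ids)
        if m.shape != (k, k):
            raise ValueError("matrix shape must match the id list")
        if (m != m.T).any() or np.diag(m).any():
            raise ValueError("matrix must be symmetric with zero diagonal")
        if m.min() < 0 or m.max() > N_STATES:
            raise ValueError(f"entries must lie in [0, {N_STATES}]")
        self.matrix = m

    def entry(self, a: str, b: str) -> int:
        return int(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        payload = {
            "ids": self.ids,
            "matrix": self.matrix.tolist(),
            "perfect": self.perfect,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                              encoding="utf-8")


def disagreement_matrix(programs: list[BoolExpr],
                        ids: list[str] | None = None) -> ReliabilityReport:
    """Exhaustive pairwise comparison over all 4,096 states."""
    if len(programs) < 2:
        raise ValueError("need at least two programs to compare")
    if ids is None:
        ids = [f"P{i + 1}" for i in range(len(programs))]
    if len(ids) != len(programs):
        raise ValueError("one id per program required")
    vectors = [truth_vector(p) for p in programs]
    k = len(programs)
    m = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = disagreement_count(vectors[i], vectors[j])
    return ReliabilityReport(list(ids), m)


def behavioral_divergence(world: GridWorld, programs: list[BoolExpr],
                          journey_length: int = 100,
                          ids: list[str] | None = None) -> pd.DataFrame:
    """Supplementary trajectory-level comparison on a given world.

    For each pair of programs and each free starting cell, counts the
    journey steps at which the two robots occupy different cells.  On an
    open world this quantifies how the truth-table disagreements cash
    out as divergent roaming behaviour.
    """
    if ids is None:
        ids = [f"P{i + 1}" for i in range(len(programs))]
    controllers = [program_controller(p) for p in programs]
    starts = world.free_cells()
    rows = []
    trajs = []
    for ctrl in controllers:
        trajs.append([
            [st.position for st in run_journey(world, ctrl, s, journey_length)]
            for s in starts])
    for i in range(len(programs)):
        for j in range(i + 1, len(programs)):
            diff_steps = [
                sum(a != b for a, b in zip(ti, tj))
                for ti, tj in zip(trajs[i], trajs[j])]
            rows.append({
                "pair": f"{ids[i]}-{ids[j]}",
                "mean_divergent_steps": float(np.mean(diff_steps)),
                "max_divergent_steps": int(np.max(diff_steps)),
                "frac_starts_divergent": float(np.mean([d > 0 for d in diff_steps])),
            })
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Configuration bundle for the end-to-end reproduction run."""

    n_gp_champions: int = 3
    gp: gp_engine.GPConfig = field(default_factory=gp_engine.GPConfig)
    nn_lambdas: tuple[float, ...] = (0.0, 0.1)
    nn_seeds: int = 5
    nn: neuroevolution.EvoConfig = field(
        default_factory=neuroevolution.EvoConfig)
    seed: int = 0


def run_full_pipeline(config: PipelineConfig,
                      out_dir: str | Path | None = None) -> ReliabilityReport:
    """Evolve GP champions, compare them with the published solutions,
    and run the lambda-sweep gate neuroevolution.

    Stages: (1) evolve ``n_gp_champions`` wall-followers on the closed
    reference labyrinth under distinct seeds derived from the pipeline
    seed; (2) verify each champion from every free start; (3) compute
    the exhaustive disagreement matrix over evolved champions plus the
    packaged Sol1-Sol3; (4) sweep lambda for the AND and XOR gate
    experiments and append champion size summaries to the provenance.
    Artifacts (program texts, matrix TSV, JSON report, manifest) are
    written when ``out_dir`` is given.
    """
    closed, _ = fixtures.reference_labyrinths()
    sol1, sol2, sol3 = fixtures.printed_solutions()
    programs = [sol1, sol2, sol3]
    ids = ["Sol1", "Sol2", "Sol3"]
    perfect: dict[str, bool] = {}
    gp_seeds = [config.seed * 1000 + i for i in range(config.n_gp_champions)]
    champions: list[gp_engine.RatedProgram] = []
    for i, seed in enumerate(gp_seeds):
        cfg = dataclasses.replace(config.gp, seed=seed)
        champ, _hist = gp_engine.evolve(cfg, closed)
        champions.append(champ)
        name = f"Evo{i + 1}"
        ids.append(name)
        programs.append(champ.program)
        perfect[name] = champ.perfect
    for name, prog in zip(("Sol1", "Sol2", "Sol3"), (sol1, sol2, sol3)):
        perfect[name] = is_perfect(closed, program_controller(prog))

    report = disagreement_matrix(programs, ids)
    report.perfect = perfect

    nn_summary = []
    and_task, xor_task = fixtures.gate_truth_tables()
    for task in (and_task, xor_task):
        for lam in config.nn_lambdas:
            sigmas, exact = [], []
            for s in range(config.nn_seeds):
                cfg = dataclasses.replace(
                    config.nn, lam=lam, seed=config.seed * 1000 + 500 + s)
                champ, _hist = neuroevolution.evolve_networks(cfg, task)
                sigmas.append(champ.sigma)
                exact.append(champ.exact)
            nn_summary.append({
                "gate": task.name, "lambda": lam,
                "median_sigma": float(np.median(sigmas)),
                "n_exact": int(sum(exact)), "n_seeds": config.nn_seeds,
            })

    report.provenance = {
        "pipeline_seed": config.seed,
        "gp_seeds": gp_seeds,
        "gp_config": {k: v for k, v in config.gp.__dict__.items()},
        "nn_summary": nn_summary,
        "nn_config": {k: v for k, v in config.nn.__dict__.items()},
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_tsv(out / "disagreement_matrix.tsv")
        report.to_json(out / "report.json")
        for name, prog in zip(ids, programs):
            (out / f"{name}.txt").write_text(serialize(prog) + "\n",
                                             encoding="utf-8")
        (out / "manifest.json").write_text(
            json.dumps(report.provenance, indent=2, default=str) + "\n",
            encoding="utf-8")
    return report
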