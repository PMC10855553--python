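"""End-to-end orchestration: pool → rank → select → average → assess.

`run_pipeline` drives the full protocol on either a synthetic benchmark case
(generated in-process with a known native) or on directories of per-frame PDB
files from real modeling runs, and emits the AVG model, an assessment report
and a provenance manifest. `run_benchmark_case` / `summarize_benchmark` are
the in-memory equivalents used by the test-suite and the reproduction script.
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .assessment import (DeltaRecord, GDTParams, LDDTParams, delta_metric,
                         fitter_fraction, gdt_ha, lddt, lddt_many,
                         wilcoxon_signed_rank)
from .averaging import AvgModel, CGParams, average_coordinates, cg_regularize
from .pool import (ConfigPool, PoolSpec, apply_gap, extract_frames, merge_runs,
                   pair_stages)
from .ranking import (Scorer, contact_scorer, external_scorer_adapter,
                      oracle_rmsd_scorer, score_pool, select_top)
from .structure_io import (Structure, read_ensemble, read_structure,
                           write_structure)
from .synthetic import (ToySpec, TrajectorySpec, make_benchmark_case,
                        make_optimized_run)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "run_benchmark_case", "summarize_benchmark", "build_pool",
           "build_avg_model"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline invocation.

    Defaults reproduce the reference protocol: stride 34, gap 1, top
    fraction 0.005, contact scorer for file inputs.
    """

    runs: list[str] = field(default_factory=list)   # dirs of per-frame PDBs, one per run
    reference: str | None = None                    # native PDB for assessment
    synthetic: bool = False                         # generate a benchmark case instead
    n_runs: int = 15
    n_residues: int = 30
    n_steps: int = 149
    stride: int = 34
    gap: int = 1
    fraction: float = 0.005
    scorer: Literal["contact", "rmsd-oracle", "external"] = "contact"
    external_cmd: str | None = None
    k_bond: float = 1.0
    k_pos: float = 0.1
    seed: int = 0
    out_dir: str = "ensavg_out"
    log_level: str = "INFO"

    def config_hash(self) -> str:
        # hash the result-affecting fields only: output location and log
        # verbosity do not change what is computed
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def build_pool(runs: Sequence[Sequence[Structure]], stride: int, gap: int,
               stage: str = "raw") -> ConfigPool:
    """Stride-extract, gap-subsample and merge per-run trajectories."""
    spec = PoolSpec(n_runs=len(runs), stride=stride, gap=gap,
                    frames_per_run=max(1, -(-len(runs[0]) // stride)))
    per_run = [apply_gap(extract_frames(run, stride, run_id=r, stage=stage), gap)
               for r, run in enumerate(runs, start=1)]
    return merge_runs(per_run, spec)


def build_avg_model(pool: ConfigPool, selection, cg_params: CGParams | None = None,
                    cg_trace: list[float] | None = None) -> tuple[AvgModel, Structure]:
    """Average the selected optimized frames and regularize the average.

    Members are passed best-rank first, so the best-ranked frame is the
    superposition target; its geometry also anchors the bond restraints.
    """
    members = [pool.frame_by_id(fid).structure for fid in selection.optimized_ids]
    avg = average_coordinates(members)
    regularized = cg_regularize(avg, members[0], cg_params, trace=cg_trace)
    return avg, regularized


def _make_scorer(config: PipelineConfig, native: Structure | None) -> Scorer:
    if config.scorer == "contact":
        return contact_scorer()
    if config.scorer == "rmsd-oracle":
        if native is None:
            raise PipelineError("rmsd-oracle scorer requires a reference structure")
        return oracle_rmsd_scorer(native)
    if config.scorer == "external":
        if not config.external_cmd:
            raise PipelineError("external scorer requires --external-cmd")
        return external_scorer_adapter(config.external_cmd)
    raise PipelineError(f"unknown scorer {config.scorer!r}")


def run_benchmark_case(case_seed: int,
                       n_runs: int = 15,
                       n_residues: int = 30,
                       n_steps: int = 149,
                       fraction: float = 0.005,
                       gap: int = 1,
                       geometry: str = "ca_trace",
                       compute_gdt: bool = True) -> dict:
    """One synthetic benchmark case, oracle-ranked, assessed against the native.

    Returns AVG and per-FINAL lDDT (and optionally GDT-HA), the Δ-records and
    the per-run fitter fractions (percentage of a run's intermediate frames
    with higher lDDT than that run's FINAL model).
    """
    toy = ToySpec(n_residues=n_residues, geometry=geometry, seed=case_seed)
    traj = TrajectorySpec(n_steps=n_steps, seed=case_seed * 1000)
    native, runs, finals = make_benchmark_case(n_runs, toy, traj)

    raw_pool = build_pool(runs, stride=1, gap=gap)
    paired = pair_stages(raw_pool, raw_pool)    # no separate optimized stage
    scored = score_pool(paired, oracle_rmsd_scorer(native))
    selection = select_top(scored, fraction)
    _, avg_structure = build_avg_model(paired, selection)

    lddt_params = LDDTParams()
    avg_lddt = lddt(avg_structure, native, lddt_params)
    final_lddts = [lddt(f, native, lddt_params) for f in finals]
    result = {
        "case_seed": case_seed,
        "n_pool": len(raw_pool),
        "n_selected": len(selection.raw_ids),
        "avg_lddt": avg_lddt,
        "final_lddts": final_lddts,
        "delta_lddt": delta_metric(avg_lddt, final_lddts, "lDDT").delta,
    }
    if compute_gdt:
        avg_gdt = gdt_ha(avg_structure, native)
        final_gdts = [gdt_ha(f, native) for f in finals]
        result.update({
            "avg_gdt_ha": avg_gdt,
            "final_gdt_has": final_gdts,
            "delta_gdt_ha": delta_metric(avg_gdt, final_gdts, "GDT_HA").delta,
        })
    # fitter fraction per run: intermediates vs the run's own FINAL, by lDDT
    fitters = []
    for run, fl in zip(runs, final_lddts):
        coords = np.stack([s.coords for s in run[:-1]])
        inter = lddt_many(coords, native, lddt_params)
        fitters.append(fitter_fraction(inter, fl, "higher_is_better"))
    result["fitter_fractions"] = fitters
    return result


def summarize_benchmark(case_seeds: Sequence[int], **case_kwargs) -> dict:
    """Aggregate benchmark cases: Δ means, fitter-fraction positivity, Wilcoxon."""
    cases = [run_benchmark_case(s, **case_kwargs) for s in case_seeds]
    delta_lddts = [c["delta_lddt"] for c in cases]
    all_fitters = [f for c in cases for f in c["fitter_fractions"]]
    fitter_pos = [all(f > 0 for f in c["fitter_fractions"]) for c in cases]
    avg_vals = [c["avg_lddt"] for c in cases]
    final_means = [float(np.mean(c["final_lddts"])) for c in cases]
    out = {
        "n_cases": len(cases),
        "mean_delta_lddt": float(np.mean(delta_lddts)),
        "mean_fitter_fraction": float(np.mean([np.mean(c["fitter_fractions"])
                                               for c in cases])),
        "pct_cases_all_runs_fitter_positive": 100.0 * float(np.mean(fitter_pos)),
        "pct_runs_fitter_positive": 100.0 * float(np.mean(np.asarray(all_fitters) > 0)),
        "wilcoxon_p_lddt": wilcoxon_signed_rank(avg_vals, final_means).p_value,
        "cases": cases,
    }
    if "delta_gdt_ha" in cases[0]:
        out["mean_delta_gdt_ha"] = float(np.mean([c["delta_gdt_ha"] for c in cases]))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full protocol and write AVG model, report and manifest."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.synthetic:
        toy = ToySpec(n_residues=config.n_residues, seed=config.seed)
        traj = TrajectorySpec(n_steps=config.n_steps, seed=config.seed * 1000)
        native, runs, finals = make_benchmark_case(config.n_runs, toy, traj)
        stride = 1
    else:
        if not config.runs:
            raise PipelineError("no run directories given and synthetic mode off")
        runs = [read_ensemble(d) for d in config.runs]
        finals = [run[-1] for run in runs]
        native = read_structure(config.reference) if config.reference else None
        stride = config.stride

    logger.info("pool: %d runs, stride %d, gap %d", len(runs), stride, config.gap)
    raw_pool = build_pool(runs, stride=stride, gap=config.gap)
    paired = pair_stages(raw_pool, raw_pool)
    scorer = _make_scorer(config, native)
    scored = score_pool(paired, scorer)
    selection = select_top(scored, config.fraction)
    logger.info("scored %d frames, selected %d (fraction %.4f)",
                len(scored.scores), len(selection.raw_ids), config.fraction)

    cg_trace: list[float] = []
    cg = CGParams(k_bond=config.k_bond, k_pos=config.k_pos)
    avg, avg_structure = build_avg_model(paired, selection, cg, cg_trace)
    avg_path = out_dir / "avg_model.pdb"
    write_structure(avg_structure, avg_path)

    report: dict = {
        "config_hash": config.config_hash(),
        "n_pool": len(raw_pool),
        "n_selected": len(selection.raw_ids),
        "selected_frames": [list(fid) for fid in selection.raw_ids],
        "avg_model": avg_path.name,
        "n_members": avg.n_members,
        "mean_spread": float(np.mean(avg.per_atom_spread)),
        "cg_iterations": max(0, len(cg_trace) - 1),
    }
    if native is not None:
        lp = LDDTParams()
        avg_l, avg_g = lddt(avg_structure, native, lp), gdt_ha(avg_structure, native)
        fin_l = [lddt(f, native, lp) for f in finals]
        fin_g = [gdt_ha(f, native) for f in finals]
        report["metrics"] = {
            "lDDT": asdict(delta_metric(avg_l, fin_l, "lDDT")),
            "GDT_HA": asdict(delta_metric(avg_g, fin_g, "GDT_HA")),
        }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "selected_frames": [list(fid) for fid in selection.raw_ids],
        "selection_scores": {str(k): v for k, v in sorted(selection.scores.items())},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
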