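"""Profile and parameter I/O, run configuration, and the staged pipeline.

Profiles travel as two-column TSV (``index<TAB>abundance``) with an
optional ``# glycan_profile`` header; the reader also tolerates deposited
mass-spectrum style two-column text (first column m/z or index, second
intensity), rank-ordering rows onto indices ``1..Ns``.  Parameter sets
are JSON.  A run configuration (JSON or YAML, schema-validated, unknown
keys rejected) drives ``run_pipeline``, which executes the requested
stages deterministically and writes a manifest.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import complexity_gmm as cx
from . import optimize as opt
from .landscape import hessian_at, probe_degeneracy
from .model import (
    GlycanProfile,
    GolgiSystem,
    ParameterSet,
    steady_state_linear,
    swap_cisternae,
)
from .objectives import kl_divergence
from .synthetic import TargetSpec, make_gmm_target, random_mixture_spec

__all__ = [
    "read_profile",
    "write_profile",
    "params_to_dict",
    "params_from_dict",
    "write_params",
    "read_params",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("golgicode")


def write_profile(path, profile: GlycanProfile) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# glycan_profile Ns={profile.Ns} "
                 f"normalized={str(profile.normalized).lower()}\n")
        for i, a in enumerate(profile.abundance, start=1):
            fh.write(f"{i}\t{float(a)!r}\n")


def read_profile(path, normalize: bool = False) -> GlycanProfile:
    """Read a glycan profile from TSV.

    Accepts the package's headered format (contiguous 1-based indices
    required) or headerless two-column text whose first column may be an
    arbitrary increasing coordinate (e.g. m/z); in the latter case rows
    are rank-ordered onto indices 1..Ns.
    """
    path = Path(path)
    header_normalized = None
    first_col, second_col = [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "glycan_profile" in line and "normalized=" in line:
                    header_normalized = "true" in line.split("normalized=")[1].lower()
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: expected two columns, got {line!r}")
            first_col.append(float(parts[0]))
            second_col.append(float(parts[1]))
    if not second_col:
        raise ValueError(f"{path}: empty profile file")
    abundance = np.asarray(second_col, dtype=float)
    if np.any(abundance < 0):
        raise ValueError(f"{path}: negative abundance encountered")
    idx = np.asarray(first_col)
    if header_normalized is not None:
        if not np.array_equal(idx, np.arange(1, idx.size + 1)):
            raise ValueError(f"{path}: indices must be contiguous and 1-based")
        prof = GlycanProfile(abundance, normalized=header_normalized)
    else:
        # deposited mass-spectrum style: rank-order onto 1..Ns
        order = np.argsort(idx, kind="stable")
        prof = GlycanProfile(abundance[order], normalized=False)
    return prof.normalize() if normalize and not prof.normalized else prof


def params_to_dict(params: ParameterSet, system: GolgiSystem | None = None) -> dict:
    d = {
        "mu": params.mu.tolist(),
        "R": params.R.tolist(),
        "L": params.L.tolist(),
        "sigma": params.sigma,
        "activity": None if params.activity is None else params.activity.tolist(),
    }
    if system is not None:
        d["bounds"] = {"mu": list(system.mu_bounds), "R": list(system.R_bounds),
                       "L": [1, system.Ns]}
    return d


def params_from_dict(d: dict) -> ParameterSet:
    return ParameterSet(
        mu=np.asarray(d["mu"], dtype=float),
        R=np.asarray(d["R"], dtype=float),
        L=np.asarray(d["L"], dtype=float),
        sigma=float(d["sigma"]),
        activity=None if d.get("activity") is None
        else np.asarray(d["activity"], dtype=float),
    )


def write_params(path, params: ParameterSet, system: GolgiSystem | None = None) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params, system), indent=2))


def read_params(path) -> ParameterSet:
    return params_from_dict(json.loads(Path(path).read_text()))


class SystemConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    NC: int = 3
    NE: int = 3
    Ns: int = 200
    q: float = 1.0
    mu_bounds: tuple[float, float] = (0.01, 1.0)
    R_bounds: tuple[float, float] = (0.018, 20.0)

    def build(self) -> GolgiSystem:
        return GolgiSystem(NC=self.NC, NE=self.NE, Ns=self.Ns, q=self.q,
                           mu_bounds=self.mu_bounds, R_bounds=self.R_bounds)


class TargetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    path: str | None = None  # profile TSV; overrides the synthetic spec
    m: int = 3  # synthetic mixture components
    seed: int = 0

    def build(self, Ns: int) -> GlycanProfile:
        if self.path is not None:
            return read_profile(self.path, normalize=True)
        return make_gmm_target(random_mixture_spec(self.m, Ns=Ns, seed=self.seed))


class OptimizerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_starts: int = 32
    maxiter: int = 200
    ftol: float = 1e-9
    sigma: float = 1.0
    sigma_grid: list[float] = Field(default_factory=lambda: [0.0, 0.5, 1.0, 2.0, 4.0])
    NE_range: list[int] = Field(default_factory=lambda: [1, 2, 3])
    NC_range: list[int] = Field(default_factory=lambda: [1, 2, 3])
    c_th: float | None = None
    m_max: int = 25
    restarts: int = 10
    hessian_step: float = 1e-3
    swap: tuple[int, int] = (2, 4)


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    stages: list[str]
    seed: int = 0
    system: SystemConfig = Field(default_factory=SystemConfig)
    target: TargetConfig = Field(default_factory=TargetConfig)
    optimizer: OptimizerConfig = Field(default_factory=OptimizerConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.model_validate(data)


_KNOWN_STAGES = ("simulate", "optimize", "scan_sigma", "tradeoff", "complexity",
                 "diversity", "landscape", "swap")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the requested stages, writing JSON/TSV outputs, a log and
    a manifest into ``out_dir``.  Deterministic given the config seed;
    stage failures are recorded and dependent stages skipped."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(_KNOWN_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    system = config.system.build()
    target = config.target.build(system.Ns)
    oc = config.optimizer
    seed = config.seed
    manifest = {"config": config.model_dump(), "stages": {}, "outputs": []}
    statuses: dict[str, str] = {}
    best_result: opt.OptimizationResult | None = None

    def record(stage: str, status: str, files: list[str]) -> None:
        statuses[stage] = status
        manifest["stages"][stage] = {"status": status, "files": files}
        manifest["outputs"].extend(files)

    write_profile(out / "target.tsv", target)
    manifest["outputs"].append("target.tsv")

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            files: list[str] = []
            if stage == "simulate":
                rng = np.random.default_rng(seed)
                params = ParameterSet(
                    mu=np.exp(rng.uniform(*np.log(system.mu_bounds), system.NC)),
                    R=np.exp(rng.uniform(*np.log(system.R_bounds),
                                         (system.NE, system.NC))),
                    L=rng.uniform(1, system.Ns, (system.NE, system.NC)),
                    sigma=oc.sigma,
                )
                ss = steady_state_linear(system, params)
                write_profile(out / "simulated_displayed.tsv", ss.displayed)
                write_params(out / "simulated_params.json", params, system)
                files = ["simulated_displayed.tsv", "simulated_params.json"]
            elif stage == "optimize":
                best_result = opt.optimize_fidelity(
                    system, target, oc.sigma, n_starts=oc.n_starts, seed=seed,
                    maxiter=oc.maxiter, ftol=oc.ftol)
                write_params(out / "optimized_params.json",
                             best_result.best_params, system)
                _write_json(out / "optimize.json", {
                    "best_F": best_result.best_F,
                    "fraction_near_best": best_result.fraction_near_best,
                    "per_start": [vars(r) for r in best_result.per_start],
                })
                disp = steady_state_linear(system, best_result.best_params).displayed
                write_profile(out / "optimized_displayed.tsv", disp)
                files = ["optimized_params.json", "optimize.json",
                         "optimized_displayed.tsv"]
            elif stage == "scan_sigma":
                scan = opt.scan_sigma(system, target, oc.sigma_grid,
                                      n_starts=oc.n_starts, seed=seed,
                                      maxiter=oc.maxiter, ftol=oc.ftol)
                _write_json(out / "sigma_scan.json", {
                    "sigma_grid": scan.sigma_grid, "Dbar": scan.Dbar,
                    "sigma_min": scan.sigma_min, "errors": scan.errors,
                })
                files = ["sigma_scan.json"]
            elif stage == "tradeoff":
                table = opt.tradeoff_surface(system, target, oc.NE_range,
                                             oc.NC_range, oc.sigma_grid,
                                             n_starts=oc.n_starts, seed=seed,
                                             maxiter=oc.maxiter, ftol=oc.ftol)
                table.to_csv(out / "tradeoff.tsv", sep="\t", index=False)
                files = ["tradeoff.tsv"]
            elif stage == "complexity":
                curve = cx.kl_curve(target, oc.m_max, restarts=oc.restarts, seed=seed)
                call = cx.call_complexity(curve)
                np.savetxt(out / "kl_curve.tsv",
                           np.column_stack([np.arange(1, curve.size + 1), curve]),
                           delimiter="\t", header="m\tkl", comments="")
                _write_json(out / "complexity.json", {
                    "m_star": call.m_star, "saturated": call.saturated,
                    "tol": call.tol, "window": call.window, "seed": seed,
                })
                files = ["kl_curve.tsv", "complexity.json"]
            elif stage == "diversity":
                res = opt.maximize_diversity(system, oc.sigma,
                                             n_starts=oc.n_starts, seed=seed,
                                             c_th=oc.c_th, maxiter=oc.maxiter)
                _write_json(out / "diversity.json", {
                    "diversity": -res.best_F, "sigma": oc.sigma,
                    "c_th": oc.c_th or 1.0 / system.Ns,
                })
                write_params(out / "diversity_params.json", res.best_params, system)
                files = ["diversity.json", "diversity_params.json"]
            elif stage == "landscape":
                if best_result is None or statuses.get("optimize") != "ok":
                    raise RuntimeError("landscape stage needs a successful "
                                       "optimize stage first")
                analysis = hessian_at(system, target, best_result.best_params,
                                      step=oc.hessian_step)
                report = probe_degeneracy(best_result,
                                          eigenvalues=analysis.eigenvalues)
                _write_json(out / "landscape.json", {
                    "dim": analysis.dim,
                    "eigenvalues": analysis.eigenvalues,
                    "groups": analysis.groups,
                    "group_stiffness": analysis.group_stiffness,
                    "total_stiffness": analysis.total_stiffness,
                    "n_clusters": report.n_clusters,
                    "fraction_near_best": report.fraction_near_best,
                    "n_flat_directions": report.n_flat_directions,
                })
                np.savetxt(out / "eigenvectors.tsv", analysis.eigenvectors,
                           delimiter="\t")
                files = ["landscape.json", "eigenvectors.tsv"]
            elif stage == "swap":
                if best_result is None or statuses.get("optimize") != "ok":
                    raise RuntimeError("swap stage needs a successful "
                                       "optimize stage first")
                j1, j2 = oc.swap
                swapped = swap_cisternae(best_result.best_params, j1, j2)
                d0 = steady_state_linear(system, best_result.best_params).displayed
                d1 = steady_state_linear(system, swapped).displayed
                _write_json(out / "swap.json", {
                    "swap": [j1, j2],
                    "kl_original_vs_swapped": kl_divergence(d0, d1),
                })
                write_profile(out / "swapped_displayed.tsv", d1)
                files = ["swap.json", "swapped_displayed.tsv"]
            record(stage, "ok", files)
            logger.info("stage %s ok (%.2fs)", stage, time.perf_counter() - t0)
        except Exception as exc:  # recorded; downstream stages may skip
            record(stage, f"failed: {exc}", [])
            logger.warning("stage %s failed: %s", stage, exc)

    _write_json(out / "manifest.json", manifest)
    return out
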