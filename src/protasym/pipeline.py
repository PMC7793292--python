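"""End-to-end orchestration: declarative config -> analyses -> JSON report.

A run config is a plain mapping (usually loaded from YAML).  Only the
stages present in the config are executed, in dependency order; a failing
stage is recorded in the report and independent stages still run.  All
randomness flows from one root seed split per stage, so adding a stage
does not perturb another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .activation import DoseResponse, fit_hill
from .errors import ConfigurationError, ProtasymError
from .pocket_metrics import (
    atom_pair_distance_series,
    distance_population,
    pocket_sasa,
    population_mass,
)
from .saxs_invariants import (
    debye_profile,
    guinier_fit,
    kratky_transform,
    pair_distance_distribution,
    porod_volume_mw,
    profile_chi2,
    rg_from_pr,
    ScatteringProfile,
)
from .structure_io import (
    AtomSelection,
    read_ensemble,
    read_structure,
    write_ensemble,
)
from .superposition import compute_rmsf
from .synthetic_data import (
    EnsembleParams,
    default_template,
    make_sphere_bead_model,
    make_two_protomer_ensemble,
)
from .vector_geometry import asymmetry_index, hinge_angles, interdomain_vector_series

logger = logging.getLogger("protasym.pipeline")

STAGES = ("ensemble", "rmsf", "vectors", "asymmetry", "hinges", "pocket", "sasa", "saxs", "hill")

# selections a stage cannot run without
_REQUIRED_KEYS = {
    "rmsf": ("align", "target"),
    "vectors": ("anchorA", "anchorB", "body_frame"),
    "asymmetry": ("protomer1", "protomer2"),
    "pocket": ("atom1", "atom2"),
    "sasa": ("residues",),
    "hill": ("data",),
    "hinges": ("segments",),
}


def selection_from_dict(d: Mapping[str, Any]) -> AtomSelection:
    """Build an AtomSelection from config keys chain/resid_range/resids/names."""
    return AtomSelection(
        chain=d.get("chain"),
        resid_range=tuple(d["resid_range"]) if d.get("resid_range") else None,
        resids=frozenset(d["resids"]) if d.get("resids") else None,
        names=frozenset(d["names"]) if d.get("names") else None,
    )


@dataclasses.dataclass
class RunConfig:
    raw: dict
    seed: int
    output_dir: Path

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        unknown = set(raw) - set(STAGES) - {"seed", "output_dir"}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            raw=raw,
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "protasym_run")),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        for stage in STAGES:
            if stage not in self.raw:
                continue
            block = self.raw[stage] or {}
            if not isinstance(block, Mapping):
                raise ConfigurationError(f"stage '{stage}' must be a mapping")
            for key in _REQUIRED_KEYS.get(stage, ()):
                if key not in block:
                    raise ConfigurationError(
                        f"stage '{stage}' is missing required key '{key}'"
                    )
        needs_traj = [
            s for s in ("rmsf", "vectors", "asymmetry", "pocket", "sasa") if s in self.raw
        ]
        if needs_traj and "ensemble" not in self.raw:
            for s in needs_traj:
                if "trajectory" not in (self.raw[s] or {}):
                    raise ConfigurationError(
                        f"stage '{s}' needs an 'ensemble' block or its own 'trajectory' path"
                    )

    def config_hash(self) -> str:
        # output_dir is excluded: it does not affect any computed number
        payload = {k: v for k, v in self.raw.items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the report."""
    config.output_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "stages": {},
        "failures": {},
    }

    traj = None
    if "ensemble" in config.raw:
        block = dict(config.raw["ensemble"] or {})
        logger.info("stage ensemble: %s", block)
        try:
            if "trajectory" in block:
                traj = read_ensemble(block["trajectory"])
                report["stages"]["ensemble"] = {
                    "source": str(block["trajectory"]),
                    "n_frames": traj.n_frames,
                    "n_atoms": traj.n_atoms,
                }
            else:
                block.setdefault("seed", _stage_seed(config.seed, "ensemble"))
                params = EnsembleParams(**block)
                traj, truth = make_two_protomer_ensemble(default_template(), params)
                write_ensemble(traj, config.output_dir / "ensemble.pdb")
                truth.to_json(config.output_dir / "ensemble_truth.json")
                report["stages"]["ensemble"] = {
                    "source": "synthetic",
                    "n_frames": traj.n_frames,
                    "n_atoms": traj.n_atoms,
                    "params": truth.params,
                }
        except (ProtasymError, TypeError) as exc:
            report["failures"]["ensemble"] = str(exc)

    def get_traj(block):
        if "trajectory" in block:
            return read_ensemble(block["trajectory"])
        if traj is None:
            raise ConfigurationError("no ensemble available for this stage")
        return traj

    if "rmsf" in config.raw:
        block = config.raw["rmsf"]
        try:
            t = get_traj(block)
            prof = compute_rmsf(
                t,
                selection_from_dict(block["align"]),
                selection_from_dict(block["target"]),
            )
            records = prof.as_records()
            _write_csv(
                config.output_dir / "rmsf.csv",
                ["chain", "resid", "rmsf_A"],
                [[r["chain"], r["resid"], f"{r['rmsf_A']:.6f}"] for r in records],
            )
            by_chain: dict[str, list[float]] = {}
            for r in records:
                by_chain.setdefault(r["chain"], []).append(r["rmsf_A"])
            report["stages"]["rmsf"] = {
                "n_residues": len(records),
                "mean_rmsf_by_chain": {c: float(np.mean(v)) for c, v in by_chain.items()},
            }
        except ProtasymError as exc:
            report["failures"]["rmsf"] = str(exc)

    vector_series: dict[str, Any] = {}
    if "vectors" in config.raw:
        block = config.raw["vectors"]
        try:
            t = get_traj(block)
            series = interdomain_vector_series(
                t,
                selection_from_dict(block["anchorA"]),
                selection_from_dict(block["anchorB"]),
                selection_from_dict(block["body_frame"]),
            )
            vector_series["default"] = series
            _write_csv(
                config.output_dir / "vectors.csv",
                ["frame", "d_A", "theta_deg", "phi_deg"],
                [
                    [i, f"{d:.4f}", f"{th:.4f}", f"{ph:.4f}"]
                    for i, (d, th, ph) in enumerate(zip(series.d, series.theta, series.phi))
                ],
            )
            report["stages"]["vectors"] = {
                "anchorA": series.anchorA_id,
                "anchorB": series.anchorB_id,
                "mean_d_A": float(series.d.mean()),
                "sd_d_A": float(series.d.std()),
                "mean_theta_deg": float(series.theta.mean()),
                "mean_phi_deg": float(series.phi.mean()),
            }
        except ProtasymError as exc:
            report["failures"]["vectors"] = str(exc)

    if "asymmetry" in config.raw:
        block = config.raw["asymmetry"]
        try:
            t = get_traj(block)
            series = []
            for key in ("protomer1", "protomer2"):
                p = block[key]
                series.append(
                    interdomain_vector_series(
                        t,
                        selection_from_dict(p["anchorA"]),
                        selection_from_dict(p["anchorB"]),
                        selection_from_dict(p["body_frame"]),
                    )
                )
            res = asymmetry_index(series[0], series[1])
            report["stages"]["asymmetry"] = {
                "delta_theta_pct": res.delta_theta,
                "delta_phi_pct": res.delta_phi,
                "delta_d_pct": res.delta_d,
                "n_frames": res.n_frames,
            }
        except (ProtasymError, KeyError) as exc:
            report["failures"]["asymmetry"] = str(exc)

    if "hinges" in config.raw:
        block = config.raw["hinges"]
        try:
            if "structure" in block:
                model = read_structure(block["structure"])[0]
            else:
                model = get_traj(block).model(0)
            segs = block["segments"]
            res = hinge_angles(
                model,
                tuple(segs["B"]),
                tuple(segs["C"]),
                tuple(segs["N"]),
                atom_name=block.get("atom_name", "CA"),
                chain=block.get("chain"),
            )
            report["stages"]["hinges"] = {
                "angle_BC_deg": res.angle_BC,
                "angle_CN_deg": res.angle_CN,
                "segment_ranges": res.segment_ranges,
            }
        except (ProtasymError, KeyError) as exc:
            report["failures"]["hinges"] = str(exc)

    if "pocket" in config.raw:
        block = config.raw["pocket"]
        try:
            t = get_traj(block)
            series = atom_pair_distance_series(
                t,
                selection_from_dict(block["atom1"]),
                selection_from_dict(block["atom2"]),
            )
            pop = distance_population(series, binwidth=block.get("binwidth", 0.1))
            _write_csv(
                config.output_dir / "pocket_population.csv",
                ["bin_center_A", "density"],
                [[f"{c:.4f}", f"{p:.6f}"] for c, p in zip(pop.bin_centers, pop.probability)],
            )
            report["stages"]["pocket"] = {
                "atom1": series.atom1_id,
                "atom2": series.atom2_id,
                "mean_distance_A": float(series.values.mean()),
                "open_mass": population_mass(pop, 6.3, 7.5),
                "closed_mass": population_mass(pop, 4.3, 5.5),
            }
        except ProtasymError as exc:
            report["failures"]["pocket"] = str(exc)

    if "sasa" in config.raw:
        block = config.raw["sasa"]
        try:
            t = get_traj(block)
            res = pocket_sasa(
                t,
                selection_from_dict(block["residues"]),
                probe_radius=block.get("probe_radius", 2.8),
                n_sphere_points=block.get("n_sphere_points", 960),
            )
            report["stages"]["sasa"] = {
                "mean_area_A2": float(res.areas.mean()),
                "sd_area_A2": float(res.areas.std()),
                "probe_radius_A": res.probe_radius,
                "n_sphere_points": res.n_sphere_points,
                "pocket_residues": res.pocket_residues,
            }
        except ProtasymError as exc:
            report["failures"]["sasa"] = str(exc)

    if "saxs" in config.raw:
        block = config.raw["saxs"]
        try:
            if "sphere" in block:
                sp = block["sphere"]
                model = make_sphere_bead_model(
                    sp["radius"],
                    sp.get("n_beads", 2000),
                    seed=sp.get("seed", _stage_seed(config.seed, "saxs")),
                )
            elif "model" in block:
                model = read_structure(block["model"])[0]
            else:
                raise ConfigurationError("stage 'saxs' needs a 'model' path or 'sphere' block")
            q = np.linspace(
                block.get("qmin", 0.005), block.get("qmax", 1.5), block.get("n_q", 600)
            )
            prof = debye_profile(model, q)
            pr = pair_distance_distribution(model, bin_width=block.get("pr_bin_width", 0.5))
            gres = guinier_fit(prof)
            # uniform-f Debye: self-scattering background is the atom count
            pres = porod_volume_mw(prof, gres.i0, background=len(model.atoms))
            kratky = kratky_transform(prof)
            entry = {
                "rg_guinier_A": gres.rg,
                "rg_from_pr_A": rg_from_pr(pr),
                "i0": gres.i0,
                "dmax_A": pr.dmax,
                "porod_volume_A3": pres.porod_volume,
                "mw_estimate_kDa": pres.mw_estimate,
                "kratky_bell_shaped": kratky.bell_shaped,
            }
            if "profile" in block:
                exp = ScatteringProfile.from_file(block["profile"])
                chi2, scale = profile_chi2(prof, exp)
                entry["chi2"] = chi2
                entry["scale"] = scale
            report["stages"]["saxs"] = entry
        except ProtasymError as exc:
            report["failures"]["saxs"] = str(exc)

    if "hill" in config.raw:
        block = config.raw["hill"]
        try:
            data = DoseResponse.from_csv(block["data"])
            fit = fit_hill(data)
            report["stages"]["hill"] = fit.as_dict()
        except (ProtasymError, FileNotFoundError) as exc:
            report["failures"]["hill"] = str(exc)

    report["ok"] = not report["failures"]
    out = config.output_dir / "report.json"
    out.write_text(json.dumps(report, indent=1, sort_keys=True, default=_json_default))
    logger.info("report written to %s", out)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")
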