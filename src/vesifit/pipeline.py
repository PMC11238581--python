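"""End-to-end orchestration: simulate → size → fit → report.

A run is described by a YAML config (seed, scenario, priors, sampler
settings, optional electrophoresis and competition stages).  Outputs are
written to a fresh run directory: the synthetic titration table, posterior
draws, a resolved-config snapshot, and a ``summary.json`` whose floating
point values are serialized at fixed precision so identical config + seed
reproduce a byte-identical artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bayes import PriorSpec, SamplerConfig, infer_posterior, summarize_posterior
from .binding import EquilibriumParams, build_calibration, competitive_equilibrium
from .errors import ConfigurationError
from .ffe import DeviceCalibration, mobilities_from_series, zeta_from_mobility
from .io import (
    load_buffer,
    load_calibration,
    load_priors,
    load_scenario,
    write_electropherograms_csv,
    write_titration_csv,
)
from .mds import ChannelGeometry
from .physchem import BufferSpec, SolventProps
from .synthetic import generate_electropherogram_series, generate_titration
from .units import parse_concentration

log = logging.getLogger("vesifit")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int
    scenario: object  # preset name, path, or dict
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    conversion: str = "auto"  # auto: calibrated for monomer, linear for oligomer
    buffer: BufferSpec = field(default_factory=BufferSpec)
    solvent: SolventProps = field(default_factory=SolventProps)
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    ffe: dict | None = None
    competition: dict | None = None

    @staticmethod
    def from_yaml(source) -> "RunConfig":
        if isinstance(source, dict):
            d = source
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        problems = []
        if "seed" not in d:
            problems.append("missing required key 'seed'")
        if "scenario" not in d:
            problems.append("missing required key 'scenario'")
        if problems:
            raise ConfigurationError("; ".join(problems))
        kwargs: dict = {"seed": int(d["seed"]), "scenario": d["scenario"]}
        if "priors" in d:
            kwargs["priors"] = load_priors(d["priors"])
        if "sampler" in d:
            kwargs["sampler"] = SamplerConfig(**d["sampler"])
        if "conversion" in d:
            kwargs["conversion"] = str(d["conversion"])
        if "buffer" in d:
            kwargs["buffer"] = load_buffer(d["buffer"])
        if "ffe" in d:
            kwargs["ffe"] = dict(d["ffe"])
        if "competition" in d:
            kwargs["competition"] = dict(d["competition"])
        return RunConfig(**kwargs)


def _round_floats(obj, sig: int = 9):
    """Round every float to ``sig`` significant digits for stable JSON."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if x == 0 or not np.isfinite(x):
            return x
        return float(f"{x:.{sig}g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the summary dict (also written as ``summary.json``).  Stage
    randomness is split deterministically from the root seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("simulate", "fit", "ffe", "competition"), root.spawn(4)
        )
    }
    summary: dict = {
        "package": "vesifit",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # --- simulate ---------------------------------------------------------
    scenario = load_scenario(config.scenario, seed=stage_seeds["simulate"])
    curve = generate_titration(scenario, config.geometry, config.solvent)
    write_titration_csv(curve, out / "titration.csv")
    log.info("simulate: %d points, species=%s", len(curve.points), scenario.species)
    summary["stages"]["simulate"] = {
        "species": scenario.species,
        "n_points": len(curve.points),
        "truth": {
            "kd_molar": scenario.truth.k_d,
            "lipids_per_site": scenario.truth.lipids_per_site,
            "b": scenario.truth.b,
        },
        "seed": stage_seeds["simulate"],
    }

    # --- fit-binding ------------------------------------------------------
    conversion = config.conversion
    if conversion == "auto":
        conversion = "calibrated" if scenario.species == "monomer" else "linear"
    calibration = None
    if conversion == "calibrated":
        calibration = build_calibration(
            curve.r_free, curve.r_bound, config.geometry, config.solvent
        )
    priors = config.priors
    if scenario.species == "oligomer" and set(priors.b_weights) == {1}:
        priors = PriorSpec(
            log10_kd_bounds=priors.log10_kd_bounds,
            log10_a_bounds=priors.log10_a_bounds,
            b_weights={b: 1.0 for b in range(30, 41)},
            sigma_max=priors.sigma_max,
        )
    post = infer_posterior(
        curve, priors, seed=stage_seeds["fit"], sampler_config=config.sampler,
        conversion=conversion, calibration=calibration,
    )
    post.draws.to_csv(out / "posterior_draws.csv", index=False)
    summ = summarize_posterior(post)
    summary["stages"]["fit_binding"] = {
        "conversion": conversion,
        "kd_molar": summ.loc["kd_molar"].to_dict(),
        "lipids_per_site": summ.loc["lipids_per_site"].to_dict(),
        "sigma": summ.loc["sigma"].to_dict(),
        "b_pmf": {str(k): v for k, v in post.b_pmf.items()},
        "diagnostics": post.diagnostics,
    }
    log.info(
        "fit-binding: K_D median %.3g M (converged=%s)",
        summ.loc["kd_molar", "median"], post.converged,
    )

    # --- ffe (optional) ---------------------------------------------------
    if config.ffe is not None:
        f = config.ffe
        cal = load_calibration(f.get("device", {})) if not isinstance(
            f.get("device"), DeviceCalibration
        ) else f["device"]
        voltages = [float(v) for v in f.get("voltages", (0.0, 20.0, 40.0, 60.0, 80.0))]
        mobilities = [float(m) for m in f["mobilities"]]
        series = generate_electropherogram_series(
            mobilities=mobilities,
            amplitudes=[1.0] * len(mobilities),
            voltages=voltages,
            cal=cal,
            noise_sd=float(f.get("noise_sd", 0.0)),
            seed=stage_seeds["ffe"],
        )
        write_electropherograms_csv(series, out / "electropherograms.csv")
        results = mobilities_from_series(series, cal, max_species=len(mobilities))
        ffe_summary = {"mobilities": [r.mobility for r in results], "seed": stage_seeds["ffe"]}
        if "radius_nm" in f:
            zeta = zeta_from_mobility(
                results[0], float(f["radius_nm"]), config.buffer, config.solvent,
                model=f.get("model", "henry"),
            )
            ffe_summary["zeta_mv"] = zeta.zeta_mv
            ffe_summary["kappa_a"] = zeta.kappa_a
            ffe_summary["model"] = zeta.model
        summary["stages"]["ffe"] = ffe_summary

    # --- competition (optional) ------------------------------------------
    if config.competition is not None:
        c = config.competition
        mono = EquilibriumParams(
            k_d=parse_concentration(c["monomer"]["kd"]),
            a=1.0 / float(c["monomer"]["lipids_per_site"]),
            b=int(c["monomer"].get("b", 1)),
        )
        olig = EquilibriumParams(
            k_d=parse_concentration(c["oligomer"]["kd"]),
            a=1.0 / float(c["oligomer"]["lipids_per_site"]),
            b=int(c["oligomer"].get("b", 35)),
        )
        lipid = parse_concentration(c["lipid_total"])
        m_tot = parse_concentration(c["monomer_total"])
        o_tot = parse_concentration(c["oligomer_total"])
        from .binding import equilibrium_fraction_bound

        f_before = equilibrium_fraction_bound(mono, lipid, m_tot)
        f_m, f_o = competitive_equilibrium(mono, olig, lipid, m_tot, o_tot)
        summary["stages"]["competition"] = {
            "monomer_fraction_before": f_before,
            "monomer_fraction_after": f_m,
            "oligomer_fraction_after": f_o,
            "displacement": f_before - f_m,
        }

    # --- report -----------------------------------------------------------
    resolved = {
        "seed": config.seed,
        "scenario": config.scenario if isinstance(config.scenario, (str, dict)) else str(config.scenario),
        "conversion": config.conversion,
        "priors": {
            "log10_kd_bounds": list(config.priors.log10_kd_bounds),
            "log10_a_bounds": list(config.priors.log10_a_bounds),
            "b_weights": {str(k): v for k, v in config.priors.b_weights.items()},
            "sigma_max": config.priors.sigma_max,
        },
        "sampler": asdict(config.sampler),
        "version": __version__,
    }
    snapshot = yaml.safe_dump(resolved, sort_keys=True)
    (out / "resolved_config.yaml").write_text(snapshot)
    summary["config_sha256"] = hashlib.sha256(snapshot.encode()).hexdigest()

    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
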