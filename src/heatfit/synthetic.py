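"""Seeded synthetic titration datasets emulating the published designs.

The generator wraps the forward heat model with a simple observation model:
a per-dataset true activity factor on the stated concentrations, a constant
per-injection dilution heat, and i.i.d. Gaussian heat noise.  Default
designs follow the study conditions: 202.8 uL cell, 20 x 2 uL injections at
288 K, ~15 uM cell / ~150 uM syringe, forward and reverse directions, and
concentration series for the global analyses.  Default noise is 0.2 ucal
per injection, typical of a low-volume calorimeter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import reference
from .errors import InvalidParameterError
from .io import write_titration
from .model import (
    Isotherm,
    TitrationExperiment,
    injection_heats,
    moles_injected_for,
)
from .thermo import KCAL, ThermoScheme

DEFAULT_SIGMA_UCAL = 0.2


@dataclass(frozen=True)
class NoiseModel:
    """Observation model applied on top of the deterministic forward heats."""

    sigma_q: float = DEFAULT_SIGMA_UCAL  # ucal per injection
    dilution_offset: float = 0.0  # ucal per injection
    activity_true: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_q < 0:
            raise InvalidParameterError("sigma_q must be >= 0")
        if not 0.0 < self.activity_true <= 1.1:
            raise InvalidParameterError("activity_true must be in (0, 1.1]")


def generate_titration(
    experiment: TitrationExperiment, scheme: ThermoScheme, noise: NoiseModel
) -> Isotherm:
    """Observed isotherm: forward heats at activity-scaled concentrations
    plus the dilution offset plus seeded Gaussian noise.  Identical seeds
    give bit-identical output."""
    sim = injection_heats(experiment.scaled(noise.activity_true), scheme)
    rng = np.random.default_rng(noise.seed)
    q = sim.q + noise.dilution_offset
    if noise.sigma_q > 0:
        q = q + rng.normal(0.0, noise.sigma_q, size=len(sim))
    # molar ratio and injected moles are reported from the *stated*
    # concentrations, as an experimenter would.
    return Isotherm(
        q=q,
        molar_ratio=sim.molar_ratio,
        moles_injected=moles_injected_for(experiment),
    )


def _design_forward(cell_uM: float, syringe_uM: float, comp_cell: int,
                    comp_syr: int, label: str) -> TitrationExperiment:
    cell = [0.0, 0.0, 0.0]
    syr = [0.0, 0.0, 0.0]
    cell[comp_cell] = cell_uM
    syr[comp_syr] = syringe_uM
    return TitrationExperiment.from_lab_units(
        tuple(cell), tuple(syr), direction_label=label
    )


def _scheme_truth(scheme: ThermoScheme) -> dict:
    out = {"scheme": scheme.scheme_id.value, "T_K": scheme.T, "parameters_kcal": {}}
    for name in scheme.active_parameters():
        v = getattr(scheme, name)
        out["parameters_kcal"][name] = v / KCAL if name.startswith("dH") else v
    return out


def study_suite_designs() -> dict[str, dict]:
    """The synthetic replicas of the published experiment classes.

    (a) hub dilution/dissociation series at three syringe concentrations;
    (b) single-site 1:1 titrations (partner-into-hub analogues);
    (c) two-mode forward series at three hub concentrations plus a reverse
        titration (RRM-less construct vs Kap);
    (d) multiple-equilibrium forward series plus reverse (intact hub core
        vs Kap);
    (e) ternary partner-into-(hub + Kap) titration.
    """
    mono = reference.monomer_dimer_scheme()
    single = reference.single_site_scheme("3")
    two = reference.two_mode_scheme()
    multi = reference.multi_eq_scheme()
    tern = reference.ternary_scheme()

    designs: dict[str, dict] = {
        "a_dissociation": {
            "scheme": mono,
            "experiments": [
                TitrationExperiment.from_lab_units(
                    (0.0, 0.0, 0.0), (c, 0.0, 0.0),
                    direction_label=f"dilution_{int(c)}uM",
                )
                for c in (300.0, 450.0, 600.0)
            ],
        },
        "b_single_site": {
            "scheme": single,
            "experiments": [_design_forward(15.0, 150.0, 0, 1, "forward")],
        },
        "c_two_mode": {
            "scheme": two,
            "experiments": [
                _design_forward(c, 10.0 * c, 0, 1, f"forward_{int(c)}uM")
                for c in (15.0, 30.0, 60.0)
            ]
            + [_design_forward(15.0, 150.0, 1, 0, "reverse")],
        },
        "d_multi_eq": {
            "scheme": multi,
            "experiments": [
                _design_forward(c, 10.0 * c, 0, 1, f"forward_{int(c)}uM")
                for c in (15.0, 30.0, 60.0)
            ]
            + [_design_forward(15.0, 150.0, 1, 0, "reverse")],
        },
        "e_ternary": {
            "scheme": tern,
            "experiments": [
                TitrationExperiment.from_lab_units(
                    (15.0, 15.0, 0.0), (0.0, 0.0, 150.0),
                    direction_label="partner_into_hub_kap",
                )
            ],
        },
    }
    return designs


def generate_study_suite(out_dir: str | Path, base_seed: int = 2019) -> dict:
    """Write the full fixture collection and return its manifest.

    Every experiment is written in a noise-free and a noisy variant with a
    deterministic per-file seed, alongside a ``truth.json`` sidecar holding
    the generating scheme.  Regenerating with the same seed is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"base_seed": base_seed, "fixtures": {}}
    seed = base_seed
    for name, design in study_suite_designs().items():
        fdir = out / name
        fdir.mkdir(exist_ok=True)
        scheme: ThermoScheme = design["scheme"]
        files = []
        for exp in design["experiments"]:
            for variant, noise in (
                ("clean", NoiseModel(sigma_q=0.0, seed=seed)),
                ("noisy", NoiseModel(sigma_q=DEFAULT_SIGMA_UCAL, seed=seed)),
            ):
                iso = generate_titration(exp, scheme, noise)
                fname = f"{exp.direction_label}_{variant}.csv"
                write_titration(fdir / fname, exp, iso)
                files.append(
                    {
                        "file": f"{name}/{fname}",
                        "variant": variant,
                        "noise": asdict(noise),
                    }
                )
            seed += 1
        sidecar = _scheme_truth(scheme)
        (fdir / "truth.json").write_text(json.dumps(sidecar, indent=2) + "\n")
        manifest["fixtures"][name] = {
            "truth": f"{name}/truth.json",
            "n_experiments": len(design["experiments"]),
            "files": files,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
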