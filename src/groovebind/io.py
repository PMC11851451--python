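"""Delimited-text I/O, unit handling, and run-configuration parsing.

All numeric tables are comma-separated UTF-8 with a mandatory header
row, "." decimal and floats written with 15 significant digits so that
write/read round trips are lossless at double precision.

Concentrations in configuration files must carry explicit units
("2 nM", "10 uM", "1e-7 M"); bare numbers are rejected to prevent
silent thousand-fold errors.  All quantities are normalized to molar
here and nowhere else.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .competition import DnaSpeciesSpec, LigandSpec, MassPeak
from .equilibrium import StepwiseConstants
from .isotherm import SteadyStateIsotherm
from .kinetics import InjectionSchedule, OneSiteKinetics, Sensorgram, TwoSiteKinetics
from .titration import TitrationCurve, TitrationDesign

__all__ = [
    "parse_concentration",
    "format_concentration",
    "write_sensorgrams",
    "read_sensorgrams",
    "write_isotherm",
    "read_isotherm",
    "write_titration_curve",
    "read_titration_curve",
    "write_spectrum",
    "read_spectrum",
    "write_report",
    "RunConfig",
    "parse_config",
    "emit_config",
    "file_digest",
]

_FLOAT_FMT = "%.15g"

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "μM": 1e-6, "nM": 1e-9, "pM": 1e-12}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([pnuµμm]?M)\s*$")


def parse_concentration(value, key: str = "concentration") -> float:
    """Parse '100 nM' style text to molar.  Bare numbers are rejected."""
    if isinstance(value, (int, float)):
        raise ValueError(
            f"{key}: bare number {value!r} — concentrations must carry units, e.g. '100 nM'"
        )
    m = _QUANTITY_RE.match(str(value))
    if not m:
        raise ValueError(f"{key}: cannot parse concentration {value!r} (expected '<number> <unit>')")
    number, unit = m.groups()
    molar = float(number) * _UNIT_SCALE[unit]
    if molar < 0:
        raise ValueError(f"{key}: concentration must be nonnegative, got {value!r}")
    return molar


def format_concentration(molar: float) -> str:
    return f"{molar:.17g} M"


# ---------------------------------------------------------------------------
# tables


def write_sensorgrams(sensorgrams: Sequence[Sensorgram], path) -> None:
    """Long-format CSV: one row per sample, schedule carried per series."""
    frames = []
    for i, sg in enumerate(sensorgrams):
        sched = sg.schedule
        frames.append(
            pd.DataFrame(
                {
                    "series": sg.label or f"series{i}",
                    "time_s": sg.time,
                    "response_RU": sg.response,
                    "concentration_M": sched.C_inject,
                    "phase": np.where(sg.time <= sched.t_stop, "association", "dissociation"),
                    "t_start_s": sched.t_start,
                    "t_stop_s": sched.t_stop,
                    "t_end_s": sched.t_end,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sensorgrams(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    required = {"series", "time_s", "response_RU", "concentration_M", "t_start_s", "t_stop_s", "t_end_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensorgram file {path} is missing columns {sorted(missing)}")
    out = []
    for label, grp in df.groupby("series", sort=False):
        sched = InjectionSchedule(
            t_start=float(grp["t_start_s"].iloc[0]),
            t_stop=float(grp["t_stop_s"].iloc[0]),
            t_end=float(grp["t_end_s"].iloc[0]),
            C_inject=float(grp["concentration_M"].iloc[0]),
        )
        out.append(
            Sensorgram(
                time=grp["time_s"].to_numpy(),
                response=grp["response_RU"].to_numpy(),
                schedule=sched,
                label=str(label),
            )
        )
    return out


def write_isotherm(iso: SteadyStateIsotherm, path) -> None:
    pd.DataFrame({"C_free_M": iso.C_free, "r": iso.r}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_isotherm(path, RUmax: float = 1.0, label: str = "") -> SteadyStateIsotherm:
    df = pd.read_csv(path)
    if "C_free_M" not in df.columns:
        raise ValueError(f"isotherm file {path} must have a C_free_M column")
    if "r" in df.columns:
        r = df["r"].to_numpy()
    elif "RU" in df.columns:
        r = df["RU"].to_numpy() / RUmax
    else:
        raise ValueError(f"isotherm file {path} needs an 'r' or 'RU' column")
    return SteadyStateIsotherm(
        C_free=df["C_free_M"].to_numpy(), r=r, RUmax=RUmax, label=label or str(path)
    )


def write_titration_curve(curve: TitrationCurve, path) -> None:
    pd.DataFrame({"ratio": curve.ratio, "signal": curve.signal}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_titration_curve(path) -> TitrationCurve:
    df = pd.read_csv(path)
    if not {"ratio", "signal"} <= set(df.columns):
        raise ValueError(f"titration file {path} needs 'ratio' and 'signal' columns")
    return TitrationCurve(ratio=df["ratio"].to_numpy(), signal=df["signal"].to_numpy())


def write_spectrum(peaks: Sequence[MassPeak], path) -> None:
    pd.DataFrame(
        {
            "mass_Da": [p.mass for p in peaks],
            "relative_intensity": [p.intensity for p in peaks],
            "species_label": [p.species for p in peaks],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectrum(path) -> list[MassPeak]:
    df = pd.read_csv(path)
    return [
        MassPeak(species=row.species_label, mass=row.mass_Da, intensity=row.relative_intensity)
        for row in df.itertuples()
    ]


def write_report(pairs: dict, path) -> None:
    """Key-value report, one 'key = value' line per entry."""
    lines = []
    for k, v in pairs.items():
        if isinstance(v, float):
            v = f"{v:.15g}"
        lines.append(f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# configuration

_COMMANDS = ("simulate", "fit", "compete", "titrate", "recover")


@dataclass
class RunConfig:
    """Validated, unit-normalized description of one pipeline run."""

    command: str
    seed: int = 0
    out: str = "."
    verbosity: int = 1
    allow_flagged: bool = False
    params: dict = field(default_factory=dict)


def _constants_from_block(block: dict, key: str) -> StepwiseConstants:
    if not isinstance(block, dict) or "model" not in block:
        raise ValueError(f"{key}: expected a mapping with a 'model' field")
    model = block["model"]
    if model == "one_site":
        if "K_A" not in block:
            raise ValueError(f"{key}: model=one_site requires K_A")
        return StepwiseConstants.one_site(float(block["K_A"]))
    if model == "two_site":
        for name in ("K_A1", "K_A2"):
            if name not in block:
                raise ValueError(f"{key}: model=two_site requires {name}")
        return StepwiseConstants.two_site(float(block["K_A1"]), float(block["K_A2"]))
    raise ValueError(f"{key}.model: unknown binding model {model!r}")


def _constants_to_block(c: StepwiseConstants) -> dict:
    if c.K_A is not None:
        return {"model": c.model.value, "K_A": float(c.K_A)}
    return {"model": c.model.value, "K_A1": float(c.K_A1), "K_A2": float(c.K_A2)}


def _kinetics_from_block(block: dict, key: str) -> OneSiteKinetics | TwoSiteKinetics:
    if not isinstance(block, dict) or "model" not in block:
        raise ValueError(f"{key}: expected a mapping with a 'model' field")
    model = block["model"]
    try:
        if model == "one_site":
            return OneSiteKinetics(
                ka=float(block["ka"]), kd=float(block["kd"]), Rmax=float(block["Rmax"])
            )
        if model == "two_site":
            return TwoSiteKinetics(
                ka1=float(block["ka1"]),
                ka2=float(block["ka2"]),
                kd1=float(block["kd1"]),
                kd2=float(block["kd2"]),
                Rmax1=float(block["Rmax1"]),
            )
    except KeyError as e:
        raise ValueError(f"{key}: missing required field {e.args[0]}") from None
    raise ValueError(f"{key}.model: unknown kinetic model {model!r}")


def _kinetics_to_block(p) -> dict:
    if isinstance(p, OneSiteKinetics):
        return {"model": "one_site", "ka": p.ka, "kd": p.kd, "Rmax": p.Rmax}
    return {"model": "two_site", "ka1": p.ka1, "ka2": p.ka2, "kd1": p.kd1, "kd2": p.kd2, "Rmax1": p.Rmax1}


_KNOWN_TOP_KEYS = {"command", "seed", "out", "verbosity", "allow_flagged", "params"}


def parse_config(source) -> RunConfig:
    """Parse and validate a YAML run configuration.

    ``source`` is a path to a config file or inline YAML text.  All
    concentrations are unit-normalized to molar here; errors name the
    offending key.
    """
    text = source
    p = Path(str(source))
    if "\n" not in str(source) and p.is_file():
        text = p.read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "command" not in raw:
        raise ValueError("config is missing required key 'command'")
    command = raw["command"]
    if command not in _COMMANDS:
        raise ValueError(f"command must be one of {_COMMANDS}, got {command!r}")
    params = dict(raw.get("params") or {})
    validated = _validate_params(command, params)
    return RunConfig(
        command=command,
        seed=int(raw.get("seed", 0)),
        out=str(raw.get("out", ".")),
        verbosity=int(raw.get("verbosity", 1)),
        allow_flagged=bool(raw.get("allow_flagged", False)),
        params=validated,
    )


def _validate_params(command: str, params: dict) -> dict:
    out = dict(params)
    if command == "simulate":
        if "kinetics" not in params:
            raise ValueError("simulate: missing params.kinetics block")
        out["kinetics"] = _kinetics_from_block(params["kinetics"], "params.kinetics")
        conc = params.get("concentrations")
        if conc is not None:
            out["concentrations"] = [
                parse_concentration(c, f"params.concentrations[{i}]") for i, c in enumerate(conc)
            ]
        out["noise_sigma_RU"] = float(params.get("noise_sigma_RU", 0.0))
    elif command == "fit":
        kind = params.get("kind")
        if kind not in ("kinetics", "isotherm"):
            raise ValueError("fit: params.kind must be 'kinetics' or 'isotherm'")
        if "input" not in params:
            raise ValueError("fit: missing params.input path")
        if kind == "isotherm":
            out["model"] = params.get("model", "two_site")
            out["RUmax"] = float(params.get("RUmax", 1.0))
    elif command == "compete":
        dna = params.get("dna")
        if not dna:
            raise ValueError("compete: missing params.dna species list")
        specs = []
        for i, block in enumerate(dna):
            key = f"params.dna[{i}]"
            if "name" not in block:
                raise ValueError(f"{key}: missing name")
            if "total" not in block:
                raise ValueError(f"{key}: missing total")
            specs.append(
                DnaSpeciesSpec(
                    name=str(block["name"]),
                    total=parse_concentration(block["total"], f"{key}.total"),
                    binding=_constants_from_block(block.get("binding"), f"{key}.binding"),
                    mass=float(block["mass_Da"]) if "mass_Da" in block else None,
                )
            )
        lig = params.get("ligand")
        if not isinstance(lig, dict) or "total" not in lig:
            raise ValueError("compete: params.ligand needs at least a total")
        out["dna"] = specs
        out["ligand"] = LigandSpec(
            name=str(lig.get("name", "ligand")),
            total=parse_concentration(lig["total"], "params.ligand.total"),
            mass=float(lig["mass_Da"]) if "mass_Da" in lig else None,
        )
    elif command == "titrate":
        design = params.get("design")
        if not isinstance(design, dict):
            raise ValueError("titrate: missing params.design block")
        for name in ("D_total", "increment", "n_steps"):
            if name not in design:
                raise ValueError(f"titrate: params.design.{name} is required")
        out["design"] = TitrationDesign(
            D_total=parse_concentration(design["D_total"], "params.design.D_total"),
            increment=parse_concentration(design["increment"], "params.design.increment"),
            n_steps=int(design["n_steps"]),
        )
        out["binding"] = _constants_from_block(params.get("binding"), "params.binding")
        out["noise_sigma"] = float(params.get("noise_sigma", 0.0))
    elif command == "recover":
        kind = params.get("kind", "isotherm")
        if kind not in ("kinetics", "isotherm"):
            raise ValueError("recover: params.kind must be 'kinetics' or 'isotherm'")
        out["kind"] = kind
        if kind == "kinetics":
            out["kinetics"] = _kinetics_from_block(
                params.get("kinetics"), "params.kinetics"
            )
            out["noise_sigma_RU"] = float(params.get("noise_sigma_RU", 0.0))
        else:
            out["constants"] = _constants_from_block(params.get("constants"), "params.constants")
            out["noise_sigma_r"] = float(params.get("noise_sigma_r", 0.0))
    return out


def emit_config(config: RunConfig) -> str:
    """Render a RunConfig back to YAML (parse(emit(cfg)) == cfg)."""
    params = {}
    for k, v in config.params.items():
        if isinstance(v, StepwiseConstants):
            params[k] = _constants_to_block(v)
        elif isinstance(v, (OneSiteKinetics, TwoSiteKinetics)):
            params[k] = _kinetics_to_block(v)
        elif isinstance(v, TitrationDesign):
            params[k] = {
                "D_total": format_concentration(v.D_total),
                "increment": format_concentration(v.increment),
                "n_steps": v.n_steps,
            }
        elif isinstance(v, LigandSpec):
            block = {"name": v.name, "total": format_concentration(v.total)}
            if v.mass is not None:
                block["mass_Da"] = v.mass
            params[k] = block
        elif k == "dna":
            params[k] = [
                {
                    "name": s.name,
                    "total": format_concentration(s.total),
                    "binding": _constants_to_block(s.binding),
                    **({"mass_Da": s.mass} if s.mass is not None else {}),
                }
                for s in v
            ]
        elif k == "concentrations":
            params[k] = [format_concentration(c) for c in v]
        else:
            params[k] = v
    return yaml.safe_dump(
        {
            "command": config.command,
            "seed": config.seed,
            "out": config.out,
            "verbosity": config.verbosity,
            "allow_flagged": config.allow_flagged,
            "params": params,
        },
        sort_keys=False,
    )
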