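"""Sectioned key=value configuration files and the bundled default fixture.

Config files are INI-style with four sections -- [blood], [bundle],
[correlation], [simulation] -- whose keys mirror the dataclass fields,
plus an optional [flows] section holding named comma-separated flow
lists.  Missing sections or keys fall back to the built-in defaults
(standard bovine-blood test conditions and the ModELAS bundle); every
override is logged.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
from dataclasses import dataclass, fields
from pathlib import Path

from .blood import BloodConstants
from .model import CO2_BENCHMARK_FLOWS, O2_BENCHMARK_FLOWS, SimulationConfig
from .transfer import BundleGeometry, CorrelationCoeffs

logger = logging.getLogger(__name__)

__all__ = ["load_config", "write_fixture_config", "RunManifest", "load_flow_lists"]

_SECTIONS = {
    "blood": BloodConstants,
    "bundle": BundleGeometry,
    "correlation": CorrelationCoeffs,
    "simulation": SimulationConfig,
}


@dataclass
class RunManifest:
    """Plain-text record of a run: config snapshot, version, outputs."""

    tool_version: str
    timestamp: str
    config_text: str
    outputs: list[str]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        lines = [
            f"tool: hfmox {self.tool_version}",
            f"timestamp: {self.timestamp}",
            "outputs:",
            *(f"  - {p}" for p in self.outputs),
            "config:",
            *("  " + ln for ln in self.config_text.splitlines()),
            "",
        ]
        path.write_text("\n".join(lines))


def _coerce(raw: str, target_type) -> object:
    if target_type is int:
        return int(raw)
    if target_type is str:
        return raw
    if raw.strip().lower() in {"none", ""}:
        return None
    return float(raw)


def load_config(
    path: str | Path | None,
) -> tuple[BloodConstants, BundleGeometry, CorrelationCoeffs, SimulationConfig]:
    """Load the four model configs, filling gaps with defaults.

    An empty or absent file yields the full defaults.  Unknown sections
    or keys raise with the list of valid names; dataclass invariants are
    enforced on construction.
    """
    parser = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    if path is not None:
        parser.read_string(Path(path).read_text())

    for section in parser.sections():
        if section not in _SECTIONS and section != "flows":
            raise ValueError(
                f"unknown config section [{section}]; valid sections: "
                f"{sorted([*_SECTIONS, 'flows'])}"
            )

    out = []
    for section, cls in _SECTIONS.items():
        valid = {f.name: f for f in fields(cls)}
        kwargs = {}
        if parser.has_section(section):
            for key, raw in parser.items(section):
                if key not in valid:
                    raise ValueError(
                        f"unknown key {key!r} in [{section}]; valid keys: {sorted(valid)}"
                    )
                f = valid[key]
                base = f.type if isinstance(f.type, type) else None
                if cls is SimulationConfig and key == "n_steps":
                    value = int(raw)
                elif cls is SimulationConfig and key == "variant":
                    value = raw
                else:
                    value = _coerce(raw, base or float)
                kwargs[key] = value
        obj = cls(**kwargs)
        default = cls()
        for key in kwargs:
            if getattr(obj, key) != getattr(default, key):
                logger.info(
                    "[%s] %s overridden: %r (default %r)",
                    section, key, getattr(obj, key), getattr(default, key),
                )
        out.append(obj)
    return tuple(out)  # type: ignore[return-value]


def load_flow_lists(path: str | Path) -> dict[str, list[float]]:
    """Read the named comma-separated flow lists from [flows], mL/min."""
    parser = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    parser.read_string(Path(path).read_text())
    if not parser.has_section("flows"):
        return {}
    return {
        name: [float(v) for v in raw.split(",")]
        for name, raw in parser.items("flows")
    }


def _fmt(value: object) -> str:
    if value is None:
        return "none"
    return repr(value)


def default_config_text() -> str:
    """The default config rendered as text; round-trips bit-exactly."""
    lines: list[str] = [
        "# hfmox model configuration: bovine-blood test conditions and the",
        "# ModELAS hollow-fiber bundle.  Units are noted per key.",
        "",
    ]
    unit_notes = {
        "blood": {
            "alpha_co2": "mL CO2 / (mL blood * mmHg)",
            "alpha_o2": "mL O2 / (mL blood * mmHg)",
            "d_co2": "cm^2/s",
            "d_hco3": "cm^2/s",
            "d_o2": "cm^2/s",
            "c_t": "mL O2 / g Hb",
            "hb": "g/dL",
            "ph": "",
            "p50": "mmHg",
            "n_hill": "",
            "nu_b": "cm^2/s",
        },
        "bundle": {
            "frontal_area": "cm^2",
            "area_per_volume": "cm^-1",
            "active_area": "cm^2",
            "fiber_od": "cm",
            "porosity": "fraction",
            "length": "cm",
            "packing_psi": "",
            "particle_diameter": "cm (none -> inferred from area_per_volume)",
        },
        "correlation": {"corr_a": "", "corr_b": ""},
        "simulation": {
            "qb": "mL/min",
            "variant": "haldane | static",
            "n_steps": "",
            "inlet_pco2": "mmHg",
            "inlet_so2": "fraction",
            "sweep_pco2": "mmHg",
            "sweep_po2": "mmHg",
        },
    }
    for section, cls in _SECTIONS.items():
        lines.append(f"[{section}]")
        obj = cls()
        for f in fields(cls):
            unit = unit_notes[section].get(f.name, "")
            comment = f"  ; {unit}" if unit else ""
            value = getattr(obj, f.name)
            rendered = value if isinstance(value, str) else _fmt(value)
            lines.append(f"{f.name} = {rendered}{comment}")
        lines.append("")
    lines.append("[flows]")
    lines.append(
        "co2_benchmark = " + ",".join(str(v) for v in CO2_BENCHMARK_FLOWS)
    )
    lines.append(
        "o2_benchmark = " + ",".join(str(v) for v in O2_BENCHMARK_FLOWS)
    )
    lines.append("")
    return "\n".join(lines)


def write_fixture_config(path: str | Path) -> RunManifest:
    """Write the default config fixture and return its manifest."""
    import datetime

    from . import __version__

    path = Path(path)
    text = default_config_text()
    path.write_text(text)
    return RunManifest(
        tool_version=__version__,
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
        config_text=text,
        outputs=[str(path)],
    )
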