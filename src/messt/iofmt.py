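"""Text-format readers/writers: session config (INI), AOI geometry,
schedules, and the per-run manifest."""

from __future__ import annotations

import configparser
import csv
import hashlib
import io
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

from .design import InvalidConfigError, SessionConfig, TrialSpec
from .geometry import AOI

__all__ = [
    "config_to_text",
    "config_from_text",
    "read_config",
    "write_config",
    "read_aoi_config",
    "write_aoi_config",
    "write_schedule",
    "read_schedule",
    "write_manifest",
]

_SESSION_KEYS_INT = {"n_trials", "n_blocks", "practice_trials"}
_SESSION_KEYS_FLOAT = {
    "stop_fraction", "ssd_init", "ssd_step", "ssd_step_escalated",
    "ssd_floor", "ssd_ceiling", "response_window", "iti",
    "fixation_enforce", "eccentricity_deg", "sampling_rate",
}


def config_to_text(config: SessionConfig) -> str:
    cp = configparser.ConfigParser()
    cp["session"] = {}
    d = asdict(config)
    for key in sorted(_SESSION_KEYS_INT | _SESSION_KEYS_FLOAT):
        cp["session"][key] = str(d[key])
    cp["session"]["categories"] = ", ".join(config.categories)
    cp["stimulus"] = {
        "width_px": str(config.stimulus_px[0]),
        "height_px": str(config.stimulus_px[1]),
    }
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def config_from_text(text: str) -> SessionConfig:
    cp = configparser.ConfigParser()
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise InvalidConfigError(f"bad config file: {exc}") from None
    kwargs = {}
    sec = cp["session"] if cp.has_section("session") else {}
    for key, val in dict(sec).items():
        if key in _SESSION_KEYS_INT:
            kwargs[key] = int(val)
        elif key in _SESSION_KEYS_FLOAT:
            kwargs[key] = float(val)
        elif key == "categories":
            kwargs[key] = tuple(c.strip() for c in val.split(",") if c.strip())
        else:
            raise InvalidConfigError(f"unknown config key {key!r}")
    if cp.has_section("stimulus"):
        kwargs["stimulus_px"] = (int(cp["stimulus"]["width_px"]),
                                 int(cp["stimulus"]["height_px"]))
    return SessionConfig(**kwargs)


def read_config(path: str | Path) -> SessionConfig:
    return config_from_text(Path(path).read_text())


def write_config(config: SessionConfig, path: str | Path) -> None:
    Path(path).write_text(config_to_text(config))


def write_aoi_config(aois: dict[str, AOI], path: str | Path) -> None:
    """AOI geometry file: one section per side with label + rect fields."""
    cp = configparser.ConfigParser()
    for side, aoi in aois.items():
        cp[side] = {
            "label": aoi.label,
            "left": f"{aoi.left:g}", "top": f"{aoi.top:g}",
            "width": f"{aoi.width:g}", "height": f"{aoi.height:g}",
        }
    with open(path, "w") as fh:
        cp.write(fh)


def read_aoi_config(path: str | Path) -> dict[str, AOI]:
    cp = configparser.ConfigParser()
    cp.read_string(Path(path).read_text())
    out = {}
    for side in cp.sections():
        sec = cp[side]
        out[side] = AOI(label=sec.get("label", side),
                        left=float(sec["left"]), top=float(sec["top"]),
                        width=float(sec["width"]), height=float(sec["height"]))
    return out


SCHEDULE_COLUMNS = ("trial", "block", "category", "side", "is_stop")


def write_schedule(schedule: list[TrialSpec], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCHEDULE_COLUMNS)
        for s in schedule:
            w.writerow([s.index, s.block, s.category, s.side,
                        "1" if s.is_stop else "0"])


def read_schedule(path: str | Path) -> list[TrialSpec]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(TrialSpec(
                index=int(row["trial"]), block=int(row["block"]),
                category=row["category"], side=row["side"],
                is_stop=row["is_stop"] == "1",
            ))
    return out


def write_manifest(path: str | Path, seed: int | None,
                   config_text: str | None,
                   inputs: dict[str, str], outputs: dict[str, str]) -> None:
    """Run manifest: seed, config hash, tool version, paths, timestamp."""
    from . import __version__
    payload = {
        "tool": "messt",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest()
        if config_text else None,
        "inputs": inputs,
        "outputs": outputs,
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
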