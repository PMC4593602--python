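"""Run configuration: interaction cutoffs, ASA threshold and I/O options.

A plain ``key = value`` file carries the same knobs the analysis exposes
programmatically; :func:`write_template` emits a fully commented template
with every default.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .interactions import DEFAULT_CUTOFFS

__all__ = ["RunConfig", "load_config", "write_template"]


@dataclasses.dataclass
class RunConfig:
    cutoffs: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    asa_threshold: float = 10.0  # % relative ASA separating buried/exposed
    sasa_points: int = 960
    model: int | None = None  # model number for multi-model files
    max_structures: int = 100

    def __post_init__(self) -> None:
        bad = [k for k, v in self.cutoffs.items() if v <= 0]
        if bad:
            raise ValueError(f"cutoffs must be positive: {bad}")
        if not 0 <= self.asa_threshold <= 100:
            raise ValueError("asa_threshold must be within [0, 100]")

    def header_lines(self) -> list[str]:
        """Effective configuration, echoed into every report."""
        lines = [f"# asa_threshold = {self.asa_threshold}",
                 f"# sasa_points = {self.sasa_points}",
                 f"# model = {self.model if self.model is not None else 'first'}"]
        for key in sorted(self.cutoffs):
            lines.append(f"# {key} = {self.cutoffs[key]}")
        return lines


_COMMENTS = {
    "ip_distance": "ion pair: charged side-chain N/O pair distance (A)",
    "aai_min": "aromatic-aromatic: minimum ring-centroid distance (A)",
    "aai_max": "aromatic-aromatic: maximum ring-centroid distance (A)",
    "asi_distance": "aromatic-sulphur: SG/SD to ring centroid (A)",
    "cpi_distance": "cation-pi: cation group to ring centroid (A)",
    "hb_distance": "hydrogen bond: donor-acceptor heavy atoms (A)",
    "hb_h_acceptor_max": "hydrogen bond: H...acceptor maximum (A)",
    "hb_angle_min": "hydrogen bond: minimum D-H...A angle (deg)",
    "hp_distance": "hydrophobic: side-chain carbon pair distance (A)",
    "disulfide_min": "disulfide: minimum SG-SG distance (A)",
    "disulfide_max": "disulfide: maximum SG-SG distance (A)",
}


def write_template(path: str | Path) -> None:
    lines = ["# analysis configuration (key = value); defaults shown", ""]
    for key, value in DEFAULT_CUTOFFS.items():
        lines.append(f"# {_COMMENTS.get(key, '')}")
        lines.append(f"{key} = {value}")
        lines.append("")
    lines += [
        "# relative ASA (%) below which a residue counts as buried",
        "asa_threshold = 10.0",
        "",
        "# sphere sample points per atom for accessible surface areas",
        "sasa_points = 960",
        "",
        "# model number for multi-model (NMR) files; omit for the first model",
        "# model = 1",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path | None) -> RunConfig:
    config = RunConfig()
    if path is None:
        return config
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = (s.strip() for s in line.partition("="))
        if key in DEFAULT_CUTOFFS:
            config.cutoffs[key] = float(value)
        elif key == "asa_threshold":
            config.asa_threshold = float(value)
        elif key == "sasa_points":
            config.sasa_points = int(value)
        elif key == "model":
            config.model = int(value)
        elif key == "max_structures":
            config.max_structures = int(value)
        else:
            raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
    config.__post_init__()
    return config
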