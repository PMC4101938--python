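"""Run configuration: every tunable of the pipeline in one flat key-value file.

The on-disk format is plain text, one ``section.key = value`` per line
(``#`` comments allowed).  A fully-defaulted configuration reproduces the
reference operating point: SVF with M = 32, Pn = 32, Vt = 8, Rmin = 10,
Rmax = 30 and 8 radius-estimation rays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

from .errors import ParameterError
from .phantoms import PhantomSpec
from .radius import RadiusParams
from .snake import SnakeParams
from .svf3d import SVFParams

__all__ = ["GvfConfig", "SeedingConfig", "IOConfig", "RunConfig", "load_config", "dump_config"]


@dataclass
class GvfConfig:
    mu: float = 0.1
    iterations: int = 50
    dt: float = 0.5
    zero_tol: float | None = None  # None -> 1e-8 of the max field magnitude


@dataclass
class SeedingConfig:
    floor: float = 0.6
    min_spacing: float = 5.0
    smoothing_sigma: float = 1.5


@dataclass
class IOConfig:
    input_path: str = ""           # TIFF stack; empty -> generate the phantom
    output_dir: str = "svftrace_out"
    normalize: bool = True
    export_fields: bool = False    # write gradient/GVF component TIFFs for debugging
    cache: bool = True


@dataclass
class PipelineExtras:
    mask_threshold: float = 0.05
    coverage_radius: float = 3.0
    merge_radius: float = 3.0
    branch_points: list = field(default_factory=list)  # [(z, y, x), ...]
    seed: int = 0


@dataclass
class RunConfig:
    io: IOConfig = field(default_factory=IOConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    gvf: GvfConfig = field(default_factory=GvfConfig)
    svf: SVFParams = field(default_factory=SVFParams)
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    snake: SnakeParams = field(default_factory=SnakeParams)
    radius: RadiusParams = field(default_factory=RadiusParams)
    run: PipelineExtras = field(default_factory=PipelineExtras)


_SECTIONS = ("io", "phantom", "gvf", "svf", "seeding", "snake", "radius", "run")


def _parse_value(raw: str, current):
    raw = raw.strip()
    if isinstance(current, bool):
        if raw.lower() in ("1", "true", "yes", "on"):
            return True
        if raw.lower() in ("0", "false", "no", "off"):
            return False
        raise ParameterError(f"expected a boolean, got {raw!r}")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    if isinstance(current, tuple):
        parts = [p for p in raw.replace(",", " ").split() if p]
        as_int = bool(current) and all(isinstance(c, int) for c in current)
        return tuple(int(p) if as_int else float(p) for p in parts)
    if isinstance(current, list):
        # branch points: semicolon-separated "z,y,x" triples
        groups = [g for g in raw.split(";") if g.strip()]
        return [tuple(float(v) for v in g.replace(",", " ").split()) for g in groups]
    if current is None:
        return float(raw)
    return raw


def load_config(path) -> RunConfig:
    """Parse a flat ``section.key = value`` file into a :class:`RunConfig`."""
    cfg = RunConfig()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"{path}:{lineno}: expected 'section.key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if "." not in key:
                raise ParameterError(f"{path}:{lineno}: key {key!r} lacks a section prefix")
            section, name = key.split(".", 1)
            if section not in _SECTIONS:
                raise ParameterError(f"{path}:{lineno}: unknown section {section!r}")
            target = getattr(cfg, section)
            if not hasattr(target, name):
                raise ParameterError(f"{path}:{lineno}: unknown key {key!r}")
            setattr(target, name, _parse_value(raw, getattr(target, name)))
    # re-validate dataclass invariants after the overrides
    for section in _SECTIONS:
        target = getattr(cfg, section)
        if hasattr(target, "__post_init__"):
            target.__post_init__()
    return cfg


def dump_config(cfg: RunConfig | None = None) -> str:
    """Render every effective parameter as ``section.key = value`` lines."""
    cfg = cfg or RunConfig()
    lines = []
    for section in _SECTIONS:
        target = getattr(cfg, section)
        for f in dc_fields(target):
            val = getattr(target, f.name)
            if isinstance(val, (tuple, list)):
                val = " ".join(str(v) for v in val)
            lines.append(f"{section}.{f.name} = {val}")
    return "\n".join(lines) + "\n"
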