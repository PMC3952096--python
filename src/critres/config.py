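"""Run configuration: every tunable of the pipeline in one flat namespace.

The config file format is flat ``key = value`` text (``#`` comments allowed);
unknown keys are rejected so typos fail loudly. Command-line flags override
file values, and every report embeds the resolved configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

__all__ = ["Config", "ConfigError", "load_config", "parse_config_text"]


class ConfigError(ValueError):
    pass


@dataclass
class Config:
    # structure_model
    covalent_tolerance: float = 0.4   # A beyond covalent radius sum
    hbond_max_distance: float = 3.5   # donor-acceptor, A
    hbond_min_angle: float = 110.0    # D-H...A degrees (explicit H only)
    hydrophobic_slack: float = 0.25   # A beyond vdW radius sum
    sasa_probe: float = 1.4           # A
    sasa_points: int = 960
    model_index: int = 0              # NMR model to read
    # mechanical_model bar policy
    hbond_bars: int = 5
    hydrophobic_bars: int = 2
    # mutagen
    mutation_target: str = "GLY"      # GLY or ALA
    tau_r: float = 0.0                # % LRB decrease threshold (strict >)
    # conservation
    tau_c: float = 0.0                # conservation score threshold (strict >)
    sigma_mode: str = "population"    # population | sample
    ranks_dialect: str = "auto"       # auto | et_server | tsv
    # experimental comparison
    ddg_window_lo: float = -10.0      # kcal/mol, inclusive
    ddg_window_hi: float = 0.0        # kcal/mol, exclusive
    # misc
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> "Config":
        if self.mutation_target.upper() not in ("GLY", "ALA"):
            raise ConfigError("mutation_target must be GLY or ALA")
        if self.sigma_mode not in ("population", "sample"):
            raise ConfigError("sigma_mode must be population or sample")
        if self.ranks_dialect not in ("auto", "et_server", "tsv"):
            raise ConfigError("ranks_dialect must be auto, et_server or tsv")
        if self.ddg_window_lo >= self.ddg_window_hi:
            raise ConfigError("ddg window lo must be < hi")
        if self.sasa_points < 16:
            raise ConfigError("sasa_points must be >= 16")
        return self


_FIELD_TYPES = {f.name: f.type for f in fields(Config)}


def parse_config_text(text: str) -> dict:
    """Parse flat key = value lines into a dict of typed values."""
    defaults = Config()
    out: dict = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"config line {ln}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(defaults, key):
            raise ConfigError(f"config line {ln}: unknown key {key!r}")
        current = getattr(defaults, key)
        try:
            if isinstance(current, bool):
                out[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                out[key] = int(value)
            elif isinstance(current, float):
                out[key] = float(value)
            else:
                out[key] = value
        except ValueError as exc:
            raise ConfigError(f"config line {ln}: {exc}") from None
    return out


def load_config(path=None, **overrides) -> Config:
    """Build a Config from an optional file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            values.update(parse_config_text(fh.read()))
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in _FIELD_TYPES:
            raise ConfigError(f"unknown config key {key!r}")
        values[key] = val
    return Config(**values).validate()
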