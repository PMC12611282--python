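"""Analysis configuration: YAML-backed, validated before any compute."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .baseline import BASELINE_METHODS

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Everything a full run needs; either an input path or a simulation.

    ``simulation`` holds keyword overrides for the default ground-truth
    spec (see :func:`specdyn.synth.default_spec`); ``input_path`` points at
    an existing container instead.  Exactly one of the two must be set.
    """

    input_path: str | None = None
    simulation: dict | None = None
    output_dir: str = "specdyn_out"
    seed: int = 0

    tfr_method: str = "superlet"
    frequencies: tuple = (3.0, 50.0, 1.0)  # start, stop (inclusive), step
    base_cycles: float = 3.0
    order_min: float = 1.0
    order_max: float = 20.0
    output_rate: float = 100.0

    subtract_erp: bool = True
    baselines: list = field(default_factory=lambda: [("decibel", (-0.5, -0.2))])

    specparam: dict = field(default_factory=dict)  # SpecparamSettings overrides
    analysis_window: tuple = (-0.5, 2.0)
    param_time_step: int = 1

    run_pacf: bool = False
    pacf_lags: tuple = (1.0, 3.0, 0.1)
    pacf_window_cycles: float = 2.5

    run_stats: bool = True
    stats_q: float = 0.05
    cluster_min: int = 3

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_path or simulation must be given"
            )
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input path {self.input_path} does not exist")
        if self.tfr_method not in ("superlet", "morlet"):
            raise ValueError(f"unknown TFR method {self.tfr_method!r}")
        start, stop, step = self.frequencies
        if not (0 < start < stop and step > 0):
            raise ValueError("frequencies must satisfy 0 < start < stop, step > 0")
        for method, window in self.baselines:
            if method not in BASELINE_METHODS:
                raise ValueError(f"unknown baseline method {method!r}")
            if not (window[0] < window[1] <= 0):
                raise ValueError(f"bad baseline window {window}")
        lo, hi = self.analysis_window
        if lo >= hi:
            raise ValueError("analysis window start must precede end")
        if not 0 < self.stats_q < 1:
            raise ValueError("stats_q must be in (0, 1)")
        if self.cluster_min < 1:
            raise ValueError("cluster_min must be >= 1")
        if self.param_time_step < 1:
            raise ValueError("param_time_step must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in ("frequencies", "analysis_window", "pacf_lags"):
            value = _tuplify(value)
        if key == "baselines":
            value = [(m, tuple(w)) for m, w in value]
        kwargs[key] = value
    config = AnalysisConfig(**kwargs)
    config.validate()
    return config
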