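"""Run configuration: defaults, TOML loading, and validation.

Every tunable of the model lives in a :class:`RunConfig` with four
sections mirroring the package layout::

    [landscape]   a, b, c, d, e
    [dynamics]    alpha, omega, epsilon, dt, m, t_max, arrival_delta,
                  no_return, jitter_sd
    [experiment]  ns, alphas, reps, master_seed, record_every
    [output]      out_dir, plots

Defaults are the published parameter set (a=1e-2, b=2, c=1, d=6, e=2e2,
epsilon=0.37, omega=3.14, n in {12, 24, 36} with m = n-1, 200 replicates).
Unknown keys are rejected rather than ignored, so a typo cannot silently
fall back to a default, and the fully resolved configuration is echoed
into every output manifest.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dynamics import DynamicsParams
from .landscape import QuarticLandscape

__all__ = ["RunConfig", "ExperimentConfig", "OutputConfig", "load_config", "config_to_dict"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Sweep shape: community sizes, alpha grid, replicates, seeding."""

    ns: tuple[int, ...] = (12, 24, 36)
    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 3))
    reps: int = 200
    master_seed: int = 0
    record_every: int = 100

    def __post_init__(self) -> None:
        if not self.ns or any(n < 1 for n in self.ns):
            raise ValueError(f"ns must be a non-empty list of positive integers, got {self.ns}")
        if not self.alphas or any(not 0.0 <= a <= 1.0 for a in self.alphas):
            raise ValueError("alphas must be a non-empty grid within [0, 1]")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.record_every < 0:
            raise ValueError(f"record_every must be >= 0, got {self.record_every}")


@dataclass(frozen=True)
class OutputConfig:
    out_dir: str = "results"
    plots: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one run, echoed into every manifest."""

    landscape: QuarticLandscape = field(default_factory=QuarticLandscape)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def __post_init__(self) -> None:
        # a fixed peer-sample size must be feasible for every community size
        if self.dynamics.m is not None:
            smallest = min(self.experiment.ns)
            if self.dynamics.m > smallest - 1:
                raise ValueError(
                    f"m={self.dynamics.m} exceeds n-1={smallest - 1} for the smallest "
                    f"community size n={smallest}"
                )


_SECTIONS = {
    "landscape": QuarticLandscape,
    "dynamics": DynamicsParams,
    "experiment": ExperimentConfig,
    "output": OutputConfig,
}

# keys that arrive from TOML as lists but are stored as tuples
_TUPLE_KEYS = {"ns", "alphas"}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in [{name}] section; "
            f"known keys: {sorted(known)}"
        )
    kwargs = {
        k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
        for k, v in data.items()
    }
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid [{name}] section: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a TOML config file, merging user overrides over the defaults.

    ``path=None`` (or an empty file) yields the full default configuration.
    Unknown sections or keys, malformed TOML, and out-of-range values all
    raise ``ValueError`` with the offending location named.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ValueError(f"malformed TOML in {path}: {exc}") from exc
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(
            f"unknown section(s) {sorted(unknown)}; known sections: {sorted(_SECTIONS)}"
        )
    sections = {
        name: _build_section(name, cls, raw.get(name, {}))
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**sections)


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain-dict form of a config, suitable for JSON manifests."""
    out = dataclasses.asdict(cfg)
    for section in out.values():
        for k, v in section.items():
            if isinstance(v, tuple):
                section[k] = list(v)
    return out
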