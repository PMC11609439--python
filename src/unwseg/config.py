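"""Declarative run configuration: one YAML file drives every command.

The file has ``model``, ``train`` and ``generator`` sections mapping onto
:class:`~unwseg.unw.ModelConfig`, :class:`~unwseg.unw.TrainConfig` and
:class:`~unwseg.synthetic.GeneratorConfig`, plus top-level ``seed`` and
``paths``.  Unknown keys are rejected; command-line flags override file
values; the effective merged config is written next to run outputs.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .synthetic import GeneratorConfig
from .unw import ModelConfig, TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTIONS = {"model": ModelConfig, "train": TrainConfig,
             "generator": GeneratorConfig}
_TOP_KEYS = {"model", "train", "generator", "seed", "paths"}


class RunConfig:
    """Merged model + train + generator config with provenance seed."""

    def __init__(self, model=None, train=None, generator=None, seed=0,
                 paths=None):
        self.model = model or ModelConfig()
        self.train = train or TrainConfig()
        self.generator = generator or GeneratorConfig()
        self.seed = int(seed)
        self.paths = dict(paths or {})

    def to_dict(self):
        d = {"model": asdict(self.model), "train": asdict(self.train),
             "generator": asdict(self.generator), "seed": self.seed,
             "paths": self.paths}
        for sec in ("model", "train", "generator"):
            for k, v in d[sec].items():
                if isinstance(v, tuple):
                    d[sec][k] = list(v)
        return d

    def with_overrides(self, **sections):
        """New RunConfig with per-section field overrides applied."""
        out = RunConfig(self.model, self.train, self.generator, self.seed,
                        self.paths)
        for sec, over in sections.items():
            if not over:
                continue
            if sec == "seed":
                out.seed = int(over)
                continue
            cls = _SECTIONS[sec]
            cur = asdict(getattr(out, sec))
            bad = set(over) - set(cur)
            if bad:
                raise KeyError(f"unknown {sec} keys {sorted(bad)}")
            cur.update(over)
            setattr(out, sec, _build(cls, cur))
        return out


def _build(cls, d):
    kwargs = {}
    for f in fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path=None, overrides=None):
    """Load a YAML run config, rejecting unknown keys."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    bad = set(data) - _TOP_KEYS
    if bad:
        raise KeyError(f"unknown config keys {sorted(bad)}")
    sections = {}
    for sec, cls in _SECTIONS.items():
        d = dict(data.get(sec) or {})
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown {sec} keys {sorted(bad)}")
        if overrides and sec in overrides:
            d.update({k: v for k, v in overrides[sec].items()
                      if v is not None})
        sections[sec] = _build(cls, d)
    seed = data.get("seed", 0)
    if overrides and overrides.get("seed") is not None:
        seed = overrides["seed"]
    return RunConfig(seed=seed, paths=data.get("paths"), **sections)


def save_config(path, cfg):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
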