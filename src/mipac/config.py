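"""Pipeline configuration: every analysis constant in one serializable place.

Defaults are the analysis constants used throughout: 0.5 Hz filter steps
(phase 0.5-10 Hz, amplitude 10-50 Hz, +/-0.5 Hz, 4th-order Butterworth),
10 equipopulated bins, 1000 permutations at alpha = 0.05, theta phase
band 3-7.5 Hz, gamma amplitude band 22-38 Hz, gamma power band 25-40 Hz,
regression p threshold 0.005.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .spectral import FilterBankSpec
from .synth import SynthParams


@dataclass
class PipelineConfig:
    fs: float = 500.0
    phase_centers: tuple[float, float, float] = (0.5, 10.0, 0.5)  # start, stop, step
    amp_centers: tuple[float, float, float] = (10.0, 50.0, 0.5)
    half_bandwidth: float = 0.5
    filter_order: int = 4
    n_bins: int = 10
    edge_trim_s: float = 1.0
    qe_seed: int = 7
    epoch_window_s: float = 2.0
    epoch_step_s: float = 1.0
    theta_phase_band: tuple[float, float] = (3.0, 7.5)
    gamma_amp_band: tuple[float, float] = (22.0, 38.0)
    gamma_power_band: tuple[float, float] = (25.0, 40.0)
    n_perm: int = 1000
    alpha: float = 0.05
    connectivity: int = 4
    regression_alpha: float = 0.005
    synth: SynthParams = field(default_factory=SynthParams)

    def filter_bank(self) -> FilterBankSpec:
        p0, p1, ps = self.phase_centers
        a0, a1, a_step = self.amp_centers
        return FilterBankSpec(
            fs=self.fs,
            centers_phase=np.arange(p0, p1 + 1e-9, ps),
            centers_amp=np.arange(a0, a1 + 1e-9, a_step),
            half_bandwidth=self.half_bandwidth,
            order=self.filter_order,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        synth = d.pop("synth")
        synth["mod_depth"] = {
            f"{g}|{lang}|{cond}": m for (g, lang, cond), m in synth["mod_depth"].items()
        }
        synth["n_per_group"] = list(synth["n_per_group"])
        d["synth"] = synth
        for key in ("phase_centers", "amp_centers", "theta_phase_band", "gamma_amp_band",
                    "gamma_power_band"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = dict(d.pop("synth", {}))
        if "mod_depth" in synth:
            depth = {}
            for key, m in synth["mod_depth"].items():
                g, lang, cond = key.split("|")
                depth[(int(g), lang, cond)] = float(m)
            synth["mod_depth"] = depth
        if "n_per_group" in synth:
            synth["n_per_group"] = tuple(synth["n_per_group"])
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name == "synth":
                continue
            if f.name in d:
                val = d[f.name]
                kwargs[f.name] = tuple(val) if isinstance(val, list) else val
        return cls(synth=SynthParams(**synth), **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
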