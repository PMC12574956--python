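"""File formats and run configuration.

Spike trains travel as plain two-column text (unit_id <TAB> spike_time_s,
with a ``# T=<seconds> N=<count>`` header) or as a JSON container that also
carries generative metadata.  Times are double-precision seconds on [0, T).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import MultiNeuronSpikeTrain

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "RunConfig",
]


class SpikeFileError(ValueError):
    pass


def write_spike_trains(train: MultiNeuronSpikeTrain, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "T": train.T,
            "N": train.N,
            "meta": {k: (v.item() if isinstance(v, np.generic) else v)
                     for k, v in train.meta.items()},
            "spikes": [s.tolist() for s in train.spikes],
        }
        path.write_text(json.dumps(payload))
        return
    lines = [f"# T={float(train.T)!r} N={train.N}"]
    for unit, s in enumerate(train.spikes):
        for t in s:
            lines.append(f"{unit}\t{float(t)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spike_trains(path) -> MultiNeuronSpikeTrain:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        T = float(payload["T"])
        spikes = [np.asarray(s, float) for s in payload["spikes"]]
        _validate(spikes, T, path)
        return MultiNeuronSpikeTrain(spikes, T=T, meta=payload.get("meta", {}))
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise SpikeFileError(f"{path}: missing '# T=... N=...' header")
    header = dict(
        kv.split("=") for kv in lines[0].lstrip("# ").split() if "=" in kv
    )
    try:
        T = float(header["T"])
        N = int(header["N"])
    except (KeyError, ValueError) as exc:
        raise SpikeFileError(f"{path}: malformed header {lines[0]!r}") from exc
    spikes = [[] for _ in range(N)]
    for ln, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SpikeFileError(f"{path}:{ln}: expected 'unit_id time'")
        try:
            unit = int(parts[0])
            t = float(parts[1])
        except ValueError as exc:
            raise SpikeFileError(f"{path}:{ln}: unparsable values") from exc
        if not 0 <= unit < N:
            raise SpikeFileError(f"{path}:{ln}: unknown unit id {unit}")
        if t < 0 or t >= T:
            raise SpikeFileError(f"{path}:{ln}: time {t} outside [0, T)")
        spikes[unit].append(t)
    arrays = [np.sort(np.asarray(s, float)) for s in spikes]
    return MultiNeuronSpikeTrain(arrays, T=T, meta={})


def _validate(spikes, T, path) -> None:
    for unit, s in enumerate(spikes):
        if s.size and (s.min() < 0 or s.max() >= T):
            raise SpikeFileError(f"{path}: unit {unit} has times outside [0, T)")


@dataclass
class RunConfig:
    """Flat run configuration; every field has a documented default and
    round-trips losslessly through the key=value config file."""

    seed: int = 0
    measure_set: str = "core"      # core | extended
    # generator defaults
    N: int = 100
    T: float = 10.0
    t_refr_neu: float = 0.004
    dt: float = 1e-5
    # spectral defaults
    kernel_bw_ms: float = 2.0
    grid_dt_ms: float = 1.0
    welch_segment_s: float = 2.0
    band_lo_hz: float = 1.0
    band_hi_hz: float = 100.0
    peak_sig_mult: float = 2.0
    # state-space defaults
    window_s: float = 30.0
    n_perm: int = 1000
    cv_scheme: str = "within"      # within | loro
    extras: dict = field(default_factory=dict)

    def save(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            if f.name == "extras":
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        for k, v in self.extras.items():
            lines.append(f"{k} = {v!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        import ast

        known = {f.name: f for f in dataclasses.fields(cls) if f.name != "extras"}
        kwargs = {}
        extras = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            value = ast.literal_eval(raw.strip())
            if key in known:
                kwargs[key] = value
            else:
                extras[key] = value
        return cls(**kwargs, extras=extras)
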