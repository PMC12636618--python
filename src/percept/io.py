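"""Configuration, seed management, and file I/O.

Audio is stored as float32 WAV at native rates (no PCM quantization of
low-RMS stimuli); trial tables as CSV with a JSON sidecar documenting the
column schema and protocol config; manifests record config, seeds and
file digests so any run can be reproduced or audited. A single top-level
seed deterministically derives all module seeds by spawning named
children of one ``SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "RunManifest", "read_wav", "write_wav", "read_config", "write_table",
    "read_table", "derive_seeds", "file_digest",
]


def write_wav(path, waveform: np.ndarray, rate: int):
    """Write float32 WAV; stereo arrays may be (2, n) or (n, 2)."""
    from scipy.io import wavfile
    w = np.asarray(waveform, dtype=np.float32)
    if w.ndim == 2 and w.shape[0] in (1, 2) and w.shape[0] < w.shape[1]:
        w = w.T
    wavfile.write(path, int(rate), w)


def read_wav(path):
    """Read a WAV file; returns (waveform, rate) with channels leading."""
    from scipy.io import wavfile
    rate, w = wavfile.read(path)
    w = np.asarray(w)
    if w.dtype.kind == "i":                       # integer PCM -> [-1, 1)
        w = w.astype(np.float64) / float(np.iinfo(w.dtype).max + 1)
    w = w.astype(np.float64)
    if w.ndim == 2:
        w = w.T
    return w, int(rate)


def read_config(path) -> dict:
    """Load a YAML config; parse errors carry the line number."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"malformed YAML in {path}{line}: {e}") from e
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_table(table, path, config: dict | None = None):
    """Write a DataFrame as CSV plus a JSON sidecar with the column schema
    (and, optionally, the protocol config)."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {"columns": {c: str(table[c].dtype) for c in table.columns},
               "n_rows": int(len(table))}
    if config is not None:
        sidecar["config"] = config
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str))
    return sidecar


def read_table(path, validate: bool = True):
    """Read a trial-table CSV; validates columns against its sidecar."""
    import pandas as pd
    path = Path(path)
    table = pd.read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if validate and sidecar_path.exists():
        schema = json.loads(sidecar_path.read_text())
        expect = list(schema.get("columns", {}))
        if list(table.columns) != expect:
            raise ValueError(
                f"{path}: columns {list(table.columns)} do not match the "
                f"sidecar schema {expect}")
    return table


def derive_seeds(top_seed: int, names: list[str]) -> dict:
    """Derive one child seed (< 2^31) per name from a top-level seed.

    Deterministic: child i is the i-th spawn of SeedSequence(top_seed),
    bound to names in order.
    """
    ss = np.random.SeedSequence(top_seed)
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % 2 ** 31)
            for name, c in zip(names, children)}


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: dict
    inputs: dict = field(default_factory=dict)    # path -> digest
    outputs: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def record_output(self, path):
        self.outputs[str(path)] = file_digest(path)

    def record_input(self, path):
        self.inputs[str(path)] = file_digest(path)

    def write(self, path):
        import percept
        self.versions.setdefault("percept", percept.__version__)
        self.versions.setdefault("numpy", np.__version__)
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         default=str))
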