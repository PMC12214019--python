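"""Plain-text file schemas: trace CSVs, manifests, results JSON.

Trace files are long-format CSV (molecule_id, frame_index, time_s,
excitation, I_D, I_A) with a JSON manifest carrying the condition, seed,
scheme hash, and optics so that a written ensemble round-trips losslessly
and byte-identically under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticScheme
from .optics import ExcitationPattern, OpticsModel
from .synth import MoleculeTrace

log = logging.getLogger(__name__)

__all__ = [
    "scheme_hash",
    "write_traces",
    "read_traces",
    "write_manifest",
    "read_manifest",
    "write_results",
]


def scheme_hash(scheme: KineticScheme) -> str:
    h = hashlib.sha256()
    h.update(",".join(scheme.state_names).encode())
    h.update(np.ascontiguousarray(scheme.rate_matrix).tobytes())
    for s in scheme.state_names:
        h.update(f"{s}:{scheme.fret_level[s]:.12g}:{scheme.donor_count[s]}".encode())
    return h.hexdigest()[:16]


def write_traces(traces: Sequence[MoleculeTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame_index": np.arange(tr.n_frames),
                    "time_s": tr.time_s,
                    "excitation": tr.excitation,
                    "I_D": tr.I_D,
                    "I_A": tr.I_A,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.4f")


def read_traces(path, frame_time: float | None = None, meta: dict | None = None) -> list[MoleculeTrace]:
    """Read a trace CSV; corrupt rows are skipped with a logged warning."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    n_raw = len(df)
    for col in ("molecule_id", "time_s", "I_D", "I_A"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["molecule_id", "time_s", "I_D", "I_A"]].isna().any(axis=1)
    bad |= df["excitation"].eq("")
    if bad.any():
        log.warning("skipped %d corrupt rows of %d in %s", int(bad.sum()), n_raw, path)
        warnings.warn(f"skipped {int(bad.sum())} corrupt rows in {path}")
        df = df[~bad]
    traces = []
    for mid, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        ft = frame_time if frame_time is not None else float(np.median(np.diff(t))) if t.size > 1 else 0.05
        traces.append(
            MoleculeTrace(
                t,
                grp["excitation"].to_numpy(dtype=object),
                grp["I_D"].to_numpy(dtype=float),
                grp["I_A"].to_numpy(dtype=float),
                ft,
                molecule_id=int(mid),
                meta=dict(meta or {}),
            )
        )
    return traces


def write_manifest(
    path,
    *,
    condition: dict,
    seed: int,
    scheme: KineticScheme,
    optics: OpticsModel,
    pattern: ExcitationPattern,
    extra: dict | None = None,
) -> None:
    payload = {
        "condition": condition,
        "seed": seed,
        "scheme_hash": scheme_hash(scheme),
        "scheme_states": list(scheme.state_names),
        "fret_levels": scheme.fret_level,
        "optics": asdict(optics),
        "pattern": asdict(pattern),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(results: dict, path) -> None:
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True, default=_jsonify))
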