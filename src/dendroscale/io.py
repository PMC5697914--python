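"""Plain-text readers and writers for the pipeline's data types."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import BranchPairRecording
from .mepsc import MepscSample

__all__ = [
    "write_mepsc_table", "read_mepsc_table",
    "write_calcium_bundle", "read_calcium_bundle",
    "write_json",
]


def write_mepsc_table(samples: list[MepscSample], path) -> None:
    """Tidy event table: cell_id, condition, amplitude_pA, rise_ms."""
    pd.concat([s.to_frame() for s in samples]).to_csv(path, sep="\t", index=False)


def read_mepsc_table(path) -> list[MepscSample]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (cell, cond), grp in df.groupby(["cell_id", "condition"], sort=False):
        out.append(MepscSample(grp["amplitude_pA"].to_numpy(),
                               grp["rise_ms"].to_numpy(),
                               cell_id=str(cell), condition=str(cond)))
    return out


def write_calcium_bundle(rec: BranchPairRecording, path) -> None:
    """JSON bundle: sampling rate plus one raw fluorescence array per ROI."""
    payload = {"rate_hz": rec.rate_hz,
               "traces": {roi: [float(v) for v in tr]
                          for roi, tr in rec.traces.items()}}
    Path(path).write_text(json.dumps(payload))


def read_calcium_bundle(path) -> BranchPairRecording:
    payload = json.loads(Path(path).read_text())
    return BranchPairRecording(
        traces={roi: np.asarray(tr, dtype=float)
                for roi, tr in payload["traces"].items()},
        rate_hz=float(payload["rate_hz"]))


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_default))
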