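"""Result serialization: spike tables, metric CSVs, and run manifests.

Spike trains are stored as tab-delimited text with columns
(population, side, trial, cell_id, time_ms), times printed with 6 decimal
places (1 ns), which round-trips losslessly for the millisecond-scale times
produced here.  A run manifest (JSON) records the tool version, resolved
configuration, seeds, timestamps, and a SHA-256 checksum per output file,
which is sufficient to re-run and to detect tampering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .network import SIDES, POPULATIONS, CircuitResult
from .periphery import SpikeTrainSet

logger = logging.getLogger("socsim")

TIME_FMT = "%.6f"


def save_spike_trains(path, train_sets) -> None:
    """Write SpikeTrainSets as a sorted tab-delimited table."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("population\tside\ttrial\tcell_id\ttime_ms\n")
        for sts in train_sets:
            for cell_id, t in enumerate(sts.trains):
                for x in np.asarray(t, dtype=float):
                    fh.write(
                        f"{sts.population}\t{sts.side}\t{sts.trial}\t{cell_id}\t"
                        f"{TIME_FMT % x}\n"
                    )


def load_spike_trains(path) -> list:
    """Read a spike table back into SpikeTrainSets (grouped, ordered)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    if df.empty:
        return out
    for (pop, side, trial), grp in df.groupby(
        ["population", "side", "trial"], sort=True
    ):
        n_cells = int(grp["cell_id"].max()) + 1
        trains = [np.empty(0)] * n_cells
        for cid, g in grp.groupby("cell_id"):
            trains[int(cid)] = np.sort(g["time_ms"].to_numpy(dtype=float))
        out.append(SpikeTrainSet(str(pop), str(side), int(trial), trains))
    return out


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(result: CircuitResult, out_dir) -> dict:
    """Persist a CircuitResult and return its manifest (also written).

    Layout: config.json (resolved config snapshot), spikes.tsv,
    metrics.csv (per-population summary), manifest.json.
    """
    from .experiments import condition_summary  # local import to avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    config_snapshot = {
        "stimulus": _to_jsonable(result.stimulus),
        "neuropathy": _to_jsonable(result.neuropathy),
        "circuit": _to_jsonable(result.config),
        "seed": result.seed,
    }
    (out / "config.json").write_text(json.dumps(config_snapshot, indent=2))

    sets = [result.spikes[(p, s, t)] for p in POPULATIONS for s in SIDES
            for t in range(result.config.n_trials)]
    save_spike_trains(out / "spikes.tsv", sets)

    summary = condition_summary(result)
    summary.to_csv(out / "metrics.csv", index=False, float_format="%.3f")

    files = ["config.json", "spikes.tsv", "metrics.csv"]
    manifest = {
        "tool": "socsim",
        "version": __version__,
        "seed": result.seed,
        "started_utc": started,
        "finished_utc": datetime.now(timezone.utc).isoformat(),
        "config": config_snapshot,
        "files": {f: sha256_of(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("wrote results to %s (seed %d)", out, result.seed)
    return manifest


def verify_manifest(out_dir) -> bool:
    """True iff every checksum in manifest.json matches the file on disk."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return all(sha256_of(out / f) == h for f, h in manifest["files"].items())
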