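"""Delimited-text input/output for pools, events, templates and recordings.

Everything is plain text so runs are portable and diffable: pool tables and
event lists as CSV, templates as two-column (time, value) files with a
small commented metadata header, multichannel recordings as TSV with a
commented rate header, and a JSON manifest capturing the config hash, seed
and library versions of a run.
"""

from __future__ import annotations

import hashlib
import json
from typing import Sequence

import numpy as np
import pandas as pd

from .core import TimeGrid
from .errors import ConfigurationError
from .motoneuron import SpikeTrain
from .templates import SpikeTemplate


def write_pool_table(pool: Sequence[dict], path) -> None:
    """Write a pool (list of unit dicts, see scenarios) as one CSV row per
    motoneuron; nested process/template fields are flattened."""
    rows = []
    for entry in pool:
        proc = entry.get("process", {})
        tmpl = entry["template"]
        rows.append(
            {
                "id": entry["id"],
                "fiber_type": entry["fiber_type"],
                "x_thr": entry["x_thr"],
                "x_sat": entry["x_sat"],
                "f_thr": entry["f_thr"],
                "f_sat": entry["f_sat"],
                "process_kind": proc.get("kind", "poisson"),
                "dispersion": proc.get("dispersion"),
                "width": proc.get("width"),
                "kernel": tmpl.get("kernel", "gaussian"),
                "derivative_order": tmpl.get("derivative_order", 1),
                "shape_params": json.dumps(tmpl.get("shape_params")),
                "duration": tmpl["duration"],
                "amplitude": tmpl["amplitude"],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pool_table(path) -> list[dict]:
    """Inverse of :func:`write_pool_table`."""
    table = pd.read_csv(path)
    pool = []
    for _, row in table.iterrows():
        proc = {"kind": row["process_kind"]}
        for key in ("dispersion", "width"):
            if pd.notna(row[key]):
                proc[key] = float(row[key])
        shape = json.loads(row["shape_params"]) if pd.notna(row["shape_params"]) else None
        pool.append(
            {
                "id": row["id"],
                "fiber_type": row["fiber_type"],
                "x_thr": float(row["x_thr"]),
                "x_sat": float(row["x_sat"]),
                "f_thr": float(row["f_thr"]),
                "f_sat": float(row["f_sat"]),
                "process": proc,
                "template": {
                    "kernel": row["kernel"],
                    "derivative_order": int(row["derivative_order"]),
                    "shape_params": shape,
                    "duration": float(row["duration"]),
                    "amplitude": float(row["amplitude"]),
                },
            }
        )
    return pool


def write_events(trains: Sequence[SpikeTrain], path) -> None:
    """Two-column event list: motoneuron_id, time_s."""
    rows = [
        {"motoneuron_id": tr.motoneuron_id, "time_s": t}
        for tr in trains
        for t in tr.event_times
    ]
    pd.DataFrame(rows, columns=["motoneuron_id", "time_s"]).to_csv(path, index=False)


def read_events(path, grid: TimeGrid) -> list[SpikeTrain]:
    table = pd.read_csv(path)
    trains = []
    for mn_id, sub in table.groupby("motoneuron_id", sort=False):
        trains.append(
            SpikeTrain(np.sort(sub["time_s"].to_numpy(float)), str(mn_id), grid)
        )
    return trains


def write_template(template: SpikeTemplate, path, grid: TimeGrid) -> None:
    """Two-column (time_s, value) text with commented metadata header."""
    times = np.arange(template.samples.size) / grid.sampling_rate
    src = template.morphology.source
    with open(path, "w") as fh:
        fh.write(f"# template_id={template.template_id}\n")
        fh.write(f"# amplitude={template.amplitude}\n")
        fh.write(f"# duration={template.duration}\n")
        fh.write(f"# morphology_class={template.morphology.morphology_class}\n")
        fh.write(f"# source={json.dumps(src)}\n")
        fh.write("time_s\tvalue\n")
        for t, v in zip(times, template.samples):
            fh.write(f"{t:.9g}\t{v:.9g}\n")


def read_template_samples(path) -> tuple[dict, np.ndarray]:
    """Read back the metadata dict and sample values of a template file."""
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        elif not line.startswith("time_s"):
            data_lines.append(line)
    values = np.array([float(line.split()[1]) for line in data_lines if line.strip()])
    return meta, values


def write_recording(values: np.ndarray, grid: TimeGrid, path, labels=None) -> None:
    """Multichannel TSV (one column per electrode) with a rate header."""
    values = np.atleast_2d(values)
    labels = labels or [f"e{k}" for k in range(values.shape[0])]
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={grid.sampling_rate}\n")
        fh.write("\t".join(str(l) for l in labels) + "\n")
        np.savetxt(fh, values.T, fmt="%.6g", delimiter="\t")


def read_recording(path) -> tuple[np.ndarray, TimeGrid, list[str]]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# sampling_rate="):
            raise ConfigurationError(
                "recording file must start with a '# sampling_rate=' line"
            )
        rate = float(header.split("=", 1)[1])
        labels = fh.readline().strip().split("\t")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    grid = TimeGrid(sampling_rate=rate, duration=values.shape[1] / rate)
    return values, grid, labels


def config_hash(cfg) -> str:
    """Stable content hash of a RunConfig."""
    return hashlib.sha256(cfg.to_yaml().encode()).hexdigest()[:16]


def write_manifest(path, cfg, summary: dict | None = None) -> None:
    """JSON manifest: config hash, seed, versions, and run summary stats."""
    import scipy

    from . import __version__

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "description": cfg.description,
        "versions": {
            "lifesim": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "summary": summary or {},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
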