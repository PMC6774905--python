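"""Event-container and configuration I/O.

Events live in an HDF5 container (``/events/<id>/{i924,i1320par,i1320perp}``
with sampling rate, label and truth attributes; decomposition results under
``/events/<id>/decomposed``) with a CSV-per-event fallback.  Scenario
configurations (beam model plus class specifications) are YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .signal import DecomposedEvent
from .simulate import CHANNELS, BeamModel, InsectClassSpec, RawEvent, TruthRecord

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_events",
    "read_events",
    "write_event_csv",
    "read_event_csv",
    "save_decomposition",
    "load_decomposition",
    "load_scenario",
    "dump_scenario",
]

SCHEMA_VERSION = "entolidar-events-1"


class SchemaError(ValueError):
    """File is not a (supported) entolidar container."""


def write_events(path, events: list[RawEvent]) -> None:
    """Write events to an HDF5 container, ids assigned by position."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = SCHEMA_VERSION
        grp = fh.create_group("events")
        for i, ev in enumerate(events):
            g = grp.create_group(f"{i:06d}")
            for ch in CHANNELS:
                g.create_dataset(ch, data=ev.channels()[ch])
            g.attrs["sampling_rate_hz"] = ev.sampling_rate_hz
            if ev.label is not None:
                g.attrs["label"] = ev.label
            if ev.truth is not None:
                for k, v in ev.truth.scalar_fields().items():
                    g.attrs[f"truth_{k}"] = v
                g.attrs["truth_label"] = ev.truth.label


def _truth_from_attrs(attrs) -> TruthRecord | None:
    if "truth_label" not in attrs:
        return None
    sigma = {}
    scalars = {}
    for k, v in attrs.items():
        if k.startswith("truth_sigma_"):
            sigma[k[len("truth_sigma_"):]] = float(v)
        elif k.startswith("truth_") and k != "truth_label":
            scalars[k[len("truth_"):]] = float(v)
    return TruthRecord(label=str(attrs["truth_label"]), sigma=sigma, **scalars)


def read_events(path) -> list[RawEvent]:
    """Read events (with labels/truth) back from an HDF5 container."""
    with h5py.File(path, "r") as fh:
        schema = fh.attrs.get("schema")
        if schema != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported event container schema {schema!r}; expected {SCHEMA_VERSION!r}"
            )
        events = []
        for key in sorted(fh["events"].keys()):
            g = fh["events"][key]
            label = g.attrs.get("label")
            events.append(
                RawEvent(
                    i924=g["i924"][:],
                    i1320par=g["i1320par"][:],
                    i1320perp=g["i1320perp"][:],
                    sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                    label=str(label) if label is not None else None,
                    truth=_truth_from_attrs(g.attrs),
                )
            )
    return events


_CSV_COLUMNS = ["t", "i924", "i1320par", "i1320perp"]


def write_event_csv(path, event: RawEvent) -> None:
    """CSV fallback for a single event (columns t, i924, i1320par, i1320perp)."""
    df = pd.DataFrame(
        {
            "t": event.time,
            "i924": event.i924,
            "i1320par": event.i1320par,
            "i1320perp": event.i1320perp,
        }
    )
    df.to_csv(path, index=False)


def read_event_csv(path) -> RawEvent:
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_COLUMNS:
        raise SchemaError(
            f"event CSV must have columns {_CSV_COLUMNS}, found {list(df.columns)}"
        )
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0]):
        raise SchemaError("event CSV time column must be uniformly sampled")
    return RawEvent(
        i924=df["i924"].to_numpy(dtype=float),
        i1320par=df["i1320par"].to_numpy(dtype=float),
        i1320perp=df["i1320perp"].to_numpy(dtype=float),
        sampling_rate_hz=1.0 / float(dt[0]),
    )


def save_decomposition(path, event_index: int, dec: DecomposedEvent) -> None:
    """Store decomposition series and cross sections next to the raw event."""
    with h5py.File(path, "a") as fh:
        g = fh["events"][f"{event_index:06d}"]
        if "decomposed" in g:
            del g["decomposed"]
        d = g.create_group("decomposed")
        for ch in CHANNELS:
            d.create_dataset(f"body_{ch}", data=dec.body(ch))
            d.create_dataset(f"wing_{ch}", data=dec.wing(ch))
        d.attrs["window_s"] = dec.window_s
        if dec.rho_assumed is not None:
            d.attrs["rho_assumed"] = dec.rho_assumed
        if dec.sigma is not None:
            for comp, val in dec.sigma.items():
                d.attrs[f"sigma_{comp}"] = val


def load_decomposition(path, event_index: int) -> DecomposedEvent:
    with h5py.File(path, "r") as fh:
        g = fh["events"][f"{event_index:06d}"]
        if "decomposed" not in g:
            raise SchemaError(f"event {event_index} has no stored decomposition")
        d = g["decomposed"]
        parts = {}
        for ch in CHANNELS:
            parts[f"body_{ch}"] = d[f"body_{ch}"][:]
            parts[f"wing_{ch}"] = d[f"wing_{ch}"][:]
        sigma = {
            k[len("sigma_"):]: float(v) for k, v in d.attrs.items() if k.startswith("sigma_")
        }
        label = g.attrs.get("label")
        return DecomposedEvent(
            sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
            window_s=float(d.attrs["window_s"]),
            label=str(label) if label is not None else None,
            sigma=sigma or None,
            rho_assumed=float(d.attrs["rho_assumed"]) if "rho_assumed" in d.attrs else None,
            **parts,
        )


# ---------------------------------------------------------------------------
# Scenario configuration (YAML)

def load_scenario(path) -> tuple[BeamModel, list[InsectClassSpec]]:
    """Read a scenario YAML: a ``beam`` mapping and a ``classes`` list whose
    entries use the InsectClassSpec field names."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "classes" not in cfg:
        raise SchemaError("scenario YAML must contain a 'classes' list")
    beam = BeamModel(**(cfg.get("beam") or {}))
    specs = [InsectClassSpec(**entry) for entry in cfg["classes"]]
    return beam, specs


def dump_scenario(path, beam: BeamModel, specs: list[InsectClassSpec]) -> None:
    cfg = {
        "beam": dataclasses.asdict(beam),
        "classes": [dataclasses.asdict(s) for s in specs],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
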