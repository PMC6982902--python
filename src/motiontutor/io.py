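"""File formats: stream CSV, pattern-bank JSON, session configuration.

All formats are plain text.  The stream CSV carries one row per tick with
the sensor-frame acceleration and the vector-first orientation quaternion;
the pattern bank is versioned JSON; the session configuration is YAML (or
JSON — YAML is a superset here) with strict key validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError
from .matching import GridAxis, MatchGrid
from .patterns import Pattern1D, PatternBank, PatternMD
from .signals import Kind, SensorStream

STREAM_COLUMNS = ["t", "sensor_id", "ax", "ay", "az", "qx", "qy", "qz", "qw"]
BANK_FORMAT_VERSION = 1
_FLOAT_FMT = "%.9g"  # lossless round-trip to 9 significant digits


# ---------------------------------------------------------------------------
# sensor streams


def write_stream(path, streams: Sequence[SensorStream] | SensorStream) -> None:
    if isinstance(streams, SensorStream):
        streams = [streams]
    frames = []
    for st in streams:
        t = np.arange(st.n) / st.sample_rate
        frames.append(
            pd.DataFrame(
                {
                    "t": t,
                    "sensor_id": st.sensor_id,
                    "ax": st.accel[:, 0],
                    "ay": st.accel[:, 1],
                    "az": st.accel[:, 2],
                    "qx": st.quats[:, 0],
                    "qy": st.quats[:, 1],
                    "qz": st.quats[:, 2],
                    "qw": st.quats[:, 3],
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_stream(path) -> List[SensorStream]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surfaced as a schema error
        raise ParseError(f"cannot parse stream CSV {path}: {exc}") from exc
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"stream CSV {path} is missing columns {missing}")
    out = []
    for sid, sub in df.groupby("sensor_id", sort=False):
        sub = sub.sort_values("t")
        t = sub["t"].to_numpy()
        if t.size < 2:
            rate = 100.0
        else:
            dt = np.diff(t)
            if np.ptp(dt) > 1e-6:
                raise ParseError(f"sensor {sid}: non-uniform sampling in {path}")
            rate = 1.0 / float(np.mean(dt))
        out.append(
            SensorStream(
                sensor_id=str(sid),
                accel=sub[["ax", "ay", "az"]].to_numpy(),
                quats=sub[["qx", "qy", "qz", "qw"]].to_numpy(),
                sample_rate=rate,
            )
        )
    if not out:
        raise ParseError(f"stream CSV {path} holds no samples")
    return out


# ---------------------------------------------------------------------------
# pattern banks


def _pattern_to_json(p: Pattern1D) -> dict:
    return {
        "w": p.w,
        "roles": sorted(p.roles),
        "kind": p.kind.value,
        "axis": p.axis,
        "sample_rate": p.sample_rate,
        "probes": [float(f"{v:.9g}") for v in p.probes],
    }


def write_bank(path, bank: PatternBank) -> None:
    doc = {
        "format_version": BANK_FORMAT_VERSION,
        "label_set": list(bank.label_set),
        "entries": [
            {
                "label": entry.label,
                "patterns": {
                    str(i): _pattern_to_json(p) for i, p in entry.members.items()
                },
            }
            for entry in bank.entries
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_bank(path) -> PatternBank:
    try:
        doc = json.loads(Path(path).read_text())
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse bank JSON {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != BANK_FORMAT_VERSION:
        raise ParseError(
            f"unsupported bank format_version {version!r} (expected {BANK_FORMAT_VERSION})"
        )
    entries = []
    for ent in doc["entries"]:
        members = {
            int(i): Pattern1D(
                index=int(i),
                probes=np.asarray(pj["probes"], dtype=float),
                roles=frozenset(pj.get("roles", ())),
                kind=Kind(pj.get("kind", "accel")),
                axis=pj.get("axis", "x"),
                sample_rate=pj.get("sample_rate", 100.0),
            )
            for i, pj in ent["patterns"].items()
        }
        entries.append(PatternMD(members=members, label=ent["label"]))
    return PatternBank(entries=entries, label_set=tuple(doc.get("label_set", ())))


# ---------------------------------------------------------------------------
# classification timelines and session logs


def write_timeline(path, rows: Sequence[dict]) -> None:
    pd.DataFrame(rows, columns=["t_start", "t_end", "label", "min_dist"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_timeline(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["t_start", "t_end", "label"] if c not in df.columns]
    if missing:
        raise ParseError(f"timeline {path} is missing columns {missing}")
    return df


def timeline_to_labels(df: pd.DataFrame, n: int, sample_rate: float, fill: str = "") -> np.ndarray:
    """Expand a segment timeline into per-sample labels."""
    labels = np.full(n, fill, dtype=object)
    for _, row in df.iterrows():
        lo = max(0, int(round(row["t_start"] * sample_rate)))
        hi = min(n, int(round(row["t_end"] * sample_rate)))
        labels[lo:hi] = row["label"]
    return labels


# ---------------------------------------------------------------------------
# session configuration


@dataclass
class SessionConfig:
    """Every tunable of a teaching/evaluation session in one place."""

    K_class: Tuple[int, ...] = (0, 2)  # accel x, accel z
    K_shape: Tuple[int, ...] = (6, 8)  # position x, position z
    fc: float = 5.0
    k: int = 3
    h_max: float = 0.05
    n_best: int = 3
    n_avg: int = 10
    len_threshold: float = 0.03
    elaps: float = 2.5
    beta: float = 0.25
    e1_range: Tuple[float, float] = (0.3, 0.9)
    e2_window_s: float = 30.0
    beta_trigger_probe: Optional[int] = None
    beta_min_spacing: Optional[float] = None
    grid: Optional[dict] = None  # MatchGrid override, serialized axis dicts
    seed: int = 0

    def match_grid(self) -> MatchGrid:
        if self.grid is None:
            return MatchGrid.default()
        g = dict(self.grid)
        kwargs = {}
        for name in ("a", "b", "c", "d"):
            if name in g and g[name] is not None:
                ax = g.pop(name)
                kwargs[name] = GridAxis(ax["lo"], ax["hi"], ax["count"])
            elif name in g:
                g.pop(name)
                kwargs[name] = None
        for name in ("b_count", "refine_factor", "n_refine_regions"):
            if name in g:
                kwargs[name] = g.pop(name)
        if g:
            raise ConfigurationError(f"unknown grid keys {sorted(g)}")
        return MatchGrid(**kwargs)

    @classmethod
    def from_file(cls, path) -> "SessionConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"session config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown session-config keys {sorted(unknown)}")
        for key in ("K_class", "K_shape", "e1_range"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_file(self, path) -> None:
        doc = asdict(self)
        doc["K_class"] = list(self.K_class)
        doc["K_shape"] = list(self.K_shape)
        doc["e1_range"] = list(self.e1_range)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
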