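"""Channel geometry, region grouping, neighbor adjacency and file I/O.

The packaged default montage is a 64-channel 10-20 extended layout on a
schematic 2-D head grid (units are electrode spacings; only relative
distances matter).  Nine scalp regions (left/medial/right ×
frontal/central/parietal) are defined for window-amplitude analysis, and
four channels (CB1, CB2, M1, M2) are excluded from network analysis.

Channel-neighbor adjacency — needed by the spatiotemporal cluster test —
is built by thresholding inter-channel Euclidean distance; the default
threshold (1.45 grid units) yields a median of ~6 neighbors per channel,
comparable to common 64-channel template neighborhoods.

Epoched EEG travels in a deliberately simple container: a flat
little-endian float32 binary array plus a JSON sidecar carrying shape,
sampling rate, epoch offset, channel names and per-trial condition
labels.  Behavioral trials and social-network files are plain CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ParameterError, ValidationError

CONDITIONS = ("peer_feedback", "non_feedback")

#: channels removed from network (node) analysis
DEFAULT_EXCLUDED = ("CB1", "CB2", "M1", "M2")


@dataclass(frozen=True)
class ChannelLayout:
    """Montage: channel names, 2-D positions, regions, exclusions, neighbors."""

    names: tuple[str, ...]
    positions: np.ndarray                # (n_channels, 2)
    regions: dict[str, tuple[str, ...]]  # region label -> channel labels
    excluded: frozenset[str]
    neighbor_threshold: float
    neighbors: np.ndarray = field(init=False)  # symmetric bool (n, n)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 2):
            raise ConfigError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.names)} channels"
            )
        known = set(self.names)
        seen: set[str] = set()
        for label, chans in self.regions.items():
            for ch in chans:
                if ch not in known:
                    raise ConfigError(
                        f"region {label!r} references unknown channel {ch!r}"
                    )
                if ch in seen:
                    raise ConfigError(
                        f"channel {ch!r} assigned to more than one region"
                    )
                seen.add(ch)
        for ch in self.excluded:
            if ch not in known:
                raise ConfigError(f"excluded channel {ch!r} not in montage")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        nb = (d <= self.neighbor_threshold) & ~np.eye(len(self.names), dtype=bool)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "neighbors", nb)

    # -- lookups ----------------------------------------------------------

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def region_of(self, name: str) -> str | None:
        for label, chans in self.regions.items():
            if name in chans:
                return label
        return None

    @property
    def retained(self) -> tuple[str, ...]:
        """Channels kept as network nodes (all names minus the exclusion set)."""
        return tuple(n for n in self.names if n not in self.excluded)

    def retained_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.names)
                         if n not in self.excluded], dtype=int)

    def region_indices(self, label: str) -> np.ndarray:
        if label not in self.regions:
            raise KeyError(f"unknown region {label!r}")
        return np.array([self.index(c) for c in self.regions[label]], dtype=int)

    def neighbor_pairs(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.neighbors))
        return [(self.names[a], self.names[b]) for a, b in zip(i, j)]


def load_layout(config_path: str | Path) -> ChannelLayout:
    """Read a montage configuration (YAML/JSON) into a :class:`ChannelLayout`.

    The file must define ``channels`` (ordered labels), ``positions``
    (label -> [x, y]), ``regions`` (label -> channel list), ``excluded``
    and ``neighbor_threshold``.
    """
    path = Path(config_path)
    with open(path) as f:
        cfg = yaml.safe_load(f)
    try:
        names = tuple(cfg["channels"])
        positions = np.array([cfg["positions"][c] for c in names], dtype=float)
        regions = {k: tuple(v) for k, v in cfg["regions"].items()}
        excluded = frozenset(cfg.get("excluded", ()))
        threshold = float(cfg.get("neighbor_threshold", 1.45))
    except KeyError as e:
        raise ConfigError(f"layout config missing key {e}") from None
    return ChannelLayout(names, positions, regions, excluded, threshold)


def default_layout() -> ChannelLayout:
    """The packaged 64-channel 10-20 montage with the nine analysis regions."""
    ref = resources.files("normnet.data").joinpath("layout_64.yaml")
    with resources.as_file(ref) as p:
        return load_layout(p)


# ---------------------------------------------------------------------------
# Epoch container
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epoched EEG: trial × channel × sample amplitudes in µV.

    ``epoch_start_ms`` is the time of sample 0 relative to stimulus onset
    (−200 by default conventions); time windows everywhere in the package
    are closed intervals in ms, inclusive of boundary samples.
    """

    amplitudes: np.ndarray            # (n_trials, n_channels, n_samples)
    srate: float                      # samples / s
    epoch_start_ms: float
    conditions: np.ndarray            # (n_trials,) of condition labels
    channels: tuple[str, ...]
    subject_id: str | None = None

    def __post_init__(self):
        a = np.asarray(self.amplitudes)
        if a.ndim != 3:
            raise FormatError(f"amplitudes must be 3-D, got shape {a.shape}")
        cond = np.asarray(self.conditions)
        if cond.shape != (a.shape[0],):
            raise FormatError(
                f"{len(cond)} condition labels for {a.shape[0]} trials"
            )
        bad = set(np.unique(cond)) - set(CONDITIONS) if len(cond) else set()
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        if a.shape[1] != len(self.channels):
            raise FormatError(
                f"array has {a.shape[1]} channels, "
                f"metadata declares {len(self.channels)}"
            )
        self.amplitudes = a
        self.conditions = cond

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.amplitudes.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.epoch_start_ms + np.arange(self.n_samples) * 1000.0 / self.srate

    def window_slice(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Indices of samples in the closed interval [start_ms, stop_ms]."""
        t = self.times_ms
        if start_ms < t[0] - 1e-9 or stop_ms > t[-1] + 1e-9:
            raise ParameterError(
                f"window [{start_ms}, {stop_ms}] ms outside epoch "
                f"[{t[0]:.1f}, {t[-1]:.1f}] ms"
            )
        return np.nonzero((t >= start_ms - 1e-9) & (t <= stop_ms + 1e-9))[0]

    def select_trials(self, index) -> "EpochSet":
        idx = np.asarray(index)
        return replace(self, amplitudes=self.amplitudes[idx],
                       conditions=self.conditions[idx])

    def condition_trials(self, condition: str) -> "EpochSet":
        return self.select_trials(np.nonzero(self.conditions == condition)[0])


def _epoch_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".json":
        p = p.with_suffix("")
    data = p if p.suffix == ".f32" else p.with_suffix(p.suffix + ".f32") \
        if p.suffix else p.with_suffix(".f32")
    return data, data.with_suffix(".json")


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an epoch set as ``<stem>.f32`` + ``<stem>.json`` sidecar.

    Amplitudes are stored as little-endian float32; a write→read
    round-trip of float32 data is bit-exact.
    """
    data_path, sidecar = _epoch_paths(path)
    data_path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(epochs.amplitudes, dtype="<f4")
    arr.tofile(data_path)
    meta = {
        "shape": list(arr.shape),
        "dtype": "<f4",
        "srate": epochs.srate,
        "epoch_start_ms": epochs.epoch_start_ms,
        "channels": list(epochs.channels),
        "conditions": [str(c) for c in epochs.conditions],
        "subject_id": epochs.subject_id,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return data_path


def read_epochs(path: str | Path) -> EpochSet:
    data_path, sidecar = _epoch_paths(path)
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    raw = np.fromfile(data_path, dtype=meta.get("dtype", "<f4"))
    if raw.size != int(np.prod(shape)):
        raise FormatError(
            f"{data_path.name}: array holds {raw.size} values but sidecar "
            f"declares shape {shape}"
        )
    return EpochSet(
        amplitudes=raw.reshape(shape),
        srate=float(meta["srate"]),
        epoch_start_ms=float(meta["epoch_start_ms"]),
        conditions=np.array(meta["conditions"], dtype=object),
        channels=tuple(meta["channels"]),
        subject_id=meta.get("subject_id"),
    )


# ---------------------------------------------------------------------------
# Behavioral / social-network CSVs
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ("subject", "stimulus", "condition", "initial", "offset",
                 "shown", "final", "rt_ms")


def read_trials(path: str | Path) -> list:
    """Read behavioral trials from CSV into :class:`~normnet.behavior.TrialRecord`s.

    Columns: ``subject,stimulus,condition,initial,offset,shown,final,rt_ms``;
    ``offset``/``shown`` are empty on non-feedback trials.  Each row is
    validated (ratings 0–9, offsets in ±{1,2,3}); violations raise
    :class:`ValidationError` naming the row.
    """
    from .behavior import TrialRecord

    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"trials file missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        feedback = row["condition"] == "peer_feedback"
        try:
            rec = TrialRecord(
                subject=str(row["subject"]),
                stimulus=str(row["stimulus"]),
                condition=str(row["condition"]),
                initial=int(row["initial"]),
                offset=int(row["offset"]) if feedback else None,
                shown=int(row["shown"]) if feedback else None,
                final=int(row["final"]),
                rt_ms=float(row["rt_ms"]),
            )
        except (ValidationError, ValueError) as e:
            raise ValidationError(f"row {i}: {e}") from None
        records.append(rec)
    return records


def write_trials(trials, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    rows = [{
        "subject": t.subject, "stimulus": t.stimulus, "condition": t.condition,
        "initial": t.initial,
        "offset": "" if t.offset is None else t.offset,
        "shown": "" if t.shown is None else t.shown,
        "final": t.final, "rt_ms": t.rt_ms,
    } for t in trials]
    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(p, index=False)
    return p


def read_social_edges(path: str | Path,
                      known_nodes=None) -> list[tuple[str, str]]:
    """Read a directed nomination edge list (CSV: ``nominator,nominee``)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("nominator", "nominee"):
        if col not in df.columns:
            raise FormatError(f"edge list missing column {col!r}")
    edges = []
    known = set(known_nodes) if known_nodes is not None else None
    for i, row in df.iterrows():
        a, b = row["nominator"], row["nominee"]
        if known is not None and (a not in known or b not in known):
            raise ValidationError(f"row {i}: edge {a}->{b} references unknown node")
        edges.append((a, b))
    return edges


def read_sizes(path: str | Path) -> dict[str, int]:
    """Read per-person real-life network-size counts (CSV: ``id,real_life_size``)."""
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "real_life_size"):
        if col not in df.columns:
            raise FormatError(f"sizes file missing column {col!r}")
    sizes = {}
    for i, row in df.iterrows():
        v = int(row["real_life_size"])
        if v < 0:
            raise ValidationError(f"row {i}: negative real-life size {v}")
        sizes[str(row["id"])] = v
    return sizes


def write_social_network(graph, edges_path: str | Path,
                         sizes_path: str | Path) -> None:
    from . import social
    assert isinstance(graph, social.SocialGraph)
    pd.DataFrame(graph.edges, columns=["nominator", "nominee"]).to_csv(
        edges_path, index=False)
    pd.DataFrame(
        {"id": list(graph.real_life_size),
         "real_life_size": list(graph.real_life_size.values())}
    ).to_csv(sizes_path, index=False)
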