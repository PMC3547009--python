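"""64-channel extended 10-20 montage and the channel-adjacency graph.

The recording cap is a 64-site Ag/AgCl extended 10-20 layout (Neuroscan
Quik-cap style) including the mastoids M1/M2 and the cerebellar leads
CB1/CB2.  Electrode positions live on the unit sphere; spatial clustering
in the permutation statistics connects channels whose great-circle
distance falls below a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Electrode",
    "Montage",
    "PAPER_CHANNELS",
    "DEFAULT_ADJACENCY_RAD",
    "build_paper_montage",
    "build_adjacency",
    "read_montage",
    "write_montage",
    "write_adjacency",
]

#: The 64 cap sites: the 62 labels enumerated for the recording montage plus
#: AF3/AF4, which the 64-channel Quik-cap carries to complete the count.
PAPER_CHANNELS: tuple[str, ...] = (
    "FPz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz",
    "FP1", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "T7", "T8",
    "C5", "C3", "C1", "C2", "C4", "C6",
    "M1", "M2",
    "TP7", "TP8",
    "CB1", "CB2",
    "CP5", "CP3", "CP1", "CP2", "CP4", "CP6",
    "P7", "P5", "P3", "P1", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "PO4", "PO6", "PO8",
    "O1", "O2",
)

#: Default neighbor threshold (radians of great-circle distance), chosen so
#: the median neighbor count on the 64-site template is in the 4-8 range
#: typical of template adjacency definitions while the off-cap mastoids keep
#: at least two neighbors each.
DEFAULT_ADJACENCY_RAD: float = 0.65

#: Cerebellar leads are absent from the 10-05 template; the conventional
#: stand-in positions are the inferior-posterior PO9/PO10 sites.
_CB_ALIASES = {"CB1": "PO9", "CB2": "PO10"}


@dataclass(frozen=True)
class Electrode:
    """A named electrode with a unit-sphere position."""

    label: str
    position: np.ndarray  # shape (3,), unit norm

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,):
            raise ValueError(f"position of {self.label!r} must be a 3-vector")
        norm = float(np.linalg.norm(pos))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(
                f"position of {self.label!r} must have unit norm (got {norm:.8f})"
            )


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set with reference and mastoid bookkeeping."""

    electrodes: tuple[Electrode, ...]
    reference_label: str = "Cz"
    mastoid_labels: tuple[str, str] = ("M1", "M2")
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            raise ValueError("electrode labels must be unique")
        for m in self.mastoid_labels:
            if m not in labels:
                raise ValueError(f"mastoid label {m!r} not in montage")
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(labels)})

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    @property
    def positions(self) -> np.ndarray:
        """(n_channels, 3) unit-sphere positions in electrode order."""
        return np.stack([e.position for e in self.electrodes])

    def __len__(self) -> int:
        return len(self.electrodes)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"channel {label!r} not in montage") from None


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit: returns (center, radius).

    Linearizes |p - c|^2 = r^2 into a linear system in (c, r^2 - |c|^2).
    """
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def build_paper_montage() -> Montage:
    """Build the 64-site cap montage with template unit-sphere positions.

    Positions come from the standard 10-05 spherical-head template,
    re-centered by a least-squares sphere fit and projected onto the unit
    sphere.  CB1/CB2 take the PO9/PO10 template positions.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        template = mne.channels.make_standard_montage("standard_1005")
    ch_pos = template.get_positions()["ch_pos"]
    by_lower = {name.lower(): pos for name, pos in ch_pos.items()}
    raw = np.stack(
        [by_lower[_CB_ALIASES.get(label, label).lower()] for label in PAPER_CHANNELS]
    )
    center, _ = _fit_sphere(raw)
    centered = raw - center
    unit = centered / np.linalg.norm(centered, axis=1, keepdims=True)
    electrodes = tuple(
        Electrode(label, pos) for label, pos in zip(PAPER_CHANNELS, unit)
    )
    return Montage(electrodes=electrodes)


def great_circle_distances(positions: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit vectors."""
    cos = np.clip(positions @ positions.T, -1.0, 1.0)
    return np.arccos(cos)


def build_adjacency(
    montage: Montage, max_angular_distance: float = DEFAULT_ADJACENCY_RAD
) -> nx.Graph:
    """Channel-adjacency graph: edge iff great-circle distance <= threshold.

    Parameters
    ----------
    montage
        Electrode set; must be non-empty.
    max_angular_distance
        Neighbor threshold in radians of arc on the unit sphere (> 0).
    """
    if len(montage) == 0:
        raise ValueError("montage has no channels")
    if max_angular_distance <= 0:
        raise ValueError("max_angular_distance must be > 0")
    labels = montage.labels
    dist = great_circle_distances(montage.positions)
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    ii, jj = np.nonzero(np.triu(dist <= max_angular_distance, k=1))
    graph.add_edges_from((labels[i], labels[j]) for i, j in zip(ii, jj))
    return graph


def write_montage(montage: Montage, path: str | Path) -> None:
    """Write a 4-column whitespace table: label x y z."""
    lines = ["# label x y z"]
    for e in montage.electrodes:
        x, y, z = e.position
        lines.append(f"{e.label} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_montage(
    path: str | Path,
    reference_label: str = "Cz",
    mastoid_labels: tuple[str, str] = ("M1", "M2"),
) -> Montage:
    """Read a montage written by :func:`write_montage`."""
    electrodes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, x, y, z = line.split()
        electrodes.append(Electrode(label, np.array([float(x), float(y), float(z)])))
    return Montage(
        electrodes=tuple(electrodes),
        reference_label=reference_label,
        mastoid_labels=mastoid_labels,
    )


def write_adjacency(graph: nx.Graph, path: str | Path) -> None:
    """Write the adjacency graph as a two-column edge list."""
    lines = [f"{a}\t{b}" for a, b in sorted(map(sorted, graph.edges()))]
    Path(path).write_text("\n".join(lines) + "\n")


def adjacency_index_pairs(graph: nx.Graph, labels: Sequence[str]) -> np.ndarray:
    """Edges as an (n_edges, 2) integer array under the given label order."""
    idx = {l: i for i, l in enumerate(labels)}
    pairs = [(idx[a], idx[b]) for a, b in graph.edges() if a in idx and b in idx]
    if not pairs:
        return np.empty((0, 2), dtype=np.intp)
    return np.asarray(pairs, dtype=np.intp)
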