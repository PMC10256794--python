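"""Core in-memory containers shared across the pipeline.

Every analysis stage exchanges one of a handful of small, validated
containers: electrode contacts (:class:`ContactSet`), multichannel time
series (:class:`TimeSeriesPanel`), square node-by-node matrices
(:class:`ConnectivityMatrix`), tractography polylines
(:class:`StreamlineSet`), 4D BOLD grids (:class:`BoldVolume`), and the
flat edge representation used by the coupling statistics
(:class:`EdgeVector`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "WmCouplingError",
    "ValidationError",
    "ContactSet",
    "TimeSeriesPanel",
    "ConnectivityMatrix",
    "StreamlineSet",
    "BoldVolume",
    "BandSpec",
    "EdgeVector",
    "CouplingResult",
    "SEEG_BANDS",
]


class WmCouplingError(Exception):
    """Base class for all package errors."""


class ValidationError(WmCouplingError):
    """A container failed its structural invariants."""


FC_MODALITIES = frozenset({"bold_fc", "seeg_fc", "coherence_fc"})
MATRIX_MODALITIES = FC_MODALITIES | {"sc", "distance"}


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValidationError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )


#: The seven SEEG analysis bands (Hz): delta through high gamma.
SEEG_BANDS: tuple[BandSpec, ...] = (
    BandSpec("1-4Hz", 1.0, 4.0),
    BandSpec("4-8Hz", 4.0, 8.0),
    BandSpec("8-13Hz", 8.0, 13.0),
    BandSpec("13-30Hz", 13.0, 30.0),
    BandSpec("30-40Hz", 30.0, 40.0),
    BandSpec("40-70Hz", 40.0, 70.0),
    BandSpec("70-170Hz", 70.0, 170.0),
)

TISSUE_LABELS = ("white", "gray", "excluded")


@dataclass(frozen=True)
class ContactSet:
    """Electrode contacts: ids, millimetre coordinates and tissue labels.

    Coordinates live in an MNI-like RAS millimetre frame.  All network
    analyses operate on the white-matter subset only.
    """

    ids: tuple[str, ...]
    coords: np.ndarray  # (n, 3) float, mm
    tissue: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "tissue", tuple(self.tissue))
        n = len(self.ids)
        if coords.shape != (n, 3):
            raise ValidationError(
                f"coords shape {coords.shape} does not match {n} contact ids"
            )
        if len(self.tissue) != n:
            raise ValidationError("tissue labels do not match contact count")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate contact ids")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite contact coordinates")
        bad = set(self.tissue) - set(TISSUE_LABELS)
        if bad:
            raise ValidationError(f"unknown tissue labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids: Sequence[str]) -> "ContactSet":
        """Return the contacts with the given ids, in this set's order."""
        keep = set(keep_ids)
        missing = keep - set(self.ids)
        if missing:
            raise ValidationError(f"unknown contact ids: {sorted(missing)}")
        idx = [k for k, cid in enumerate(self.ids) if cid in keep]
        return ContactSet(
            ids=tuple(self.ids[k] for k in idx),
            coords=self.coords[idx],
            tissue=tuple(self.tissue[k] for k in idx),
        )

    def white_matter(self) -> "ContactSet":
        """The white-matter contacts, the nodes of every network here."""
        idx = [k for k, t in enumerate(self.tissue) if t == "white"]
        if not idx:
            raise ValidationError("no white-matter contacts")
        return ContactSet(
            ids=tuple(self.ids[k] for k in idx),
            coords=self.coords[idx],
            tissue=tuple(self.tissue[k] for k in idx),
        )


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Channels x samples at a fixed sampling rate.

    ``modality`` tags the carrier: ``"seeg"`` for local field potentials,
    ``"bold"`` for ROI-averaged fMRI series.
    """

    values: np.ndarray  # (n_channels, n_samples)
    fs: float  # Hz
    channel_ids: tuple[str, ...]
    modality: str = "seeg"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_ids", tuple(str(c) for c in self.channel_ids))
        if values.ndim != 2:
            raise ValidationError("panel values must be 2-D (channels x samples)")
        if values.shape[0] != len(self.channel_ids):
            raise ValidationError(
                f"{values.shape[0]} rows but {len(self.channel_ids)} channel ids"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("duplicate channel ids")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Panel duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    def with_values(self, values: np.ndarray) -> "TimeSeriesPanel":
        return replace(self, values=values)

    def subset(self, keep_ids: Sequence[str]) -> "TimeSeriesPanel":
        keep = set(keep_ids)
        missing = keep - set(self.channel_ids)
        if missing:
            raise ValidationError(f"unknown channel ids: {sorted(missing)}")
        idx = [k for k, cid in enumerate(self.channel_ids) if cid in keep]
        return TimeSeriesPanel(
            values=self.values[idx],
            fs=self.fs,
            channel_ids=tuple(self.channel_ids[k] for k in idx),
            modality=self.modality,
        )


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node x node matrix with modality (and optional band) tags.

    Functional connectivity (Pearson r) lies in [-1, 1] with unit
    diagonal; coherence in [0, 1]; structural connectivity is a
    nonnegative streamline count with zero diagonal; distance is in mm
    with zero diagonal.
    """

    values: np.ndarray
    nodes: tuple[str, ...]
    modality: str
    band: str | None = None

    _SYM_TOL = 1e-10

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "nodes", tuple(str(n) for n in self.nodes))
        n = len(self.nodes)
        if values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {values.shape} does not match {n} nodes"
            )
        if len(set(self.nodes)) != n:
            raise ValidationError("duplicate node ids")
        if self.modality not in MATRIX_MODALITIES:
            raise ValidationError(f"unknown matrix modality {self.modality!r}")
        finite = np.isfinite(values)
        if not finite.all() and self.modality in {"sc", "distance"}:
            raise ValidationError(f"non-finite values in {self.modality} matrix")
        # NaN entries are allowed in FC matrices (flagged undefined channels);
        # symmetry is checked on the finite entries.
        both = finite & finite.T
        asym = np.abs(np.where(both, values - values.T, 0.0)).max(initial=0.0)
        if asym > self._SYM_TOL:
            raise ValidationError(f"matrix asymmetric (max |a-a'| = {asym:g})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def subset(self, keep_ids: Sequence[str]) -> "ConnectivityMatrix":
        keep = set(keep_ids)
        idx = [k for k, nid in enumerate(self.nodes) if nid in keep]
        if len(idx) != len(keep):
            raise ValidationError("subset ids not all present in matrix")
        sub = self.values[np.ix_(idx, idx)]
        return ConnectivityMatrix(
            values=sub,
            nodes=tuple(self.nodes[k] for k in idx),
            modality=self.modality,
            band=self.band,
        )


@dataclass(frozen=True)
class StreamlineSet:
    """Tractography streamlines: polylines of millimetre points."""

    streamlines: tuple[np.ndarray, ...]  # each (k, 3), k >= 2

    def __post_init__(self) -> None:
        lines = tuple(np.asarray(s, dtype=float) for s in self.streamlines)
        object.__setattr__(self, "streamlines", lines)
        for k, line in enumerate(lines):
            if line.ndim != 2 or line.shape[1] != 3 or line.shape[0] < 2:
                raise ValidationError(f"streamline {k}: need (>=2, 3) points")
            if not np.all(np.isfinite(line)):
                raise ValidationError(f"streamline {k}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass(frozen=True)
class BoldVolume:
    """A 4D BOLD grid (x, y, z, t) on an isotropic voxel lattice."""

    data: np.ndarray  # (nx, ny, nz, nt)
    voxel_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tr: float = 2.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        origin = np.asarray(self.origin_mm, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "origin_mm", origin)
        if data.ndim != 4:
            raise ValidationError("BOLD volume must be 4-D (x, y, z, t)")
        if data.shape[3] < 2:
            raise ValidationError("BOLD volume needs at least 2 time points")
        if not self.voxel_mm > 0:
            raise ValidationError("voxel size must be positive")
        if not self.tr > 0:
            raise ValidationError("TR must be positive")
        if origin.shape != (3,):
            raise ValidationError("origin must be a 3-vector (mm)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class EdgeVector:
    """Half-vectorized edge values over unordered contact pairs.

    ``pair_index`` lists the (i, j) node-index pairs, i < j, in strict
    lexicographic order of the parent matrix's node ordering (possibly
    masked to a subset of pairs).
    """

    values: np.ndarray  # (n_edges,)
    pair_index: np.ndarray  # (n_edges, 2) int
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        pairs = np.asarray(self.pair_index, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pair_index", pairs)
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if values.ndim != 1 or pairs.shape != (values.size, 2):
            raise ValidationError("edge values and pair index sizes disagree")
        if values.size:
            if np.any(pairs[:, 0] >= pairs[:, 1]):
                raise ValidationError("pair index must satisfy i < j")
            order = pairs[:, 0] * len(self.nodes) + pairs[:, 1]
            if np.any(np.diff(order) <= 0):
                raise ValidationError("pair index must be strictly lexicographic")

    @property
    def n_edges(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CouplingResult:
    """One distance-residualized Spearman comparison for one participant."""

    participant: str
    band: str  # band label, or "bold" for the SC-vs-BOLD comparison
    comparison: str  # bold_vs_seeg | sc_vs_seeg | sc_vs_bold
    r: float
    p: float
    n_edges: int

    def __post_init__(self) -> None:
        if self.n_edges < 4:
            raise ValidationError("coupling result needs at least 4 edges")
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError(f"Spearman r out of range: {self.r}")
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"p-value out of range: {self.p}")
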