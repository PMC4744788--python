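"""Core data containers for irregular spatiotemporal monitoring data.

Monitoring data consist of concentration measurements taken from a network
of wells at irregular dates.  Each observation carries a well identifier,
two spatial coordinates (easting/northing in site units) and a time
coordinate (fractional days since the earliest sample, or the simulator's
model time).  Concentrations are analysed on the ``log(y + offset)`` scale;
the offset guards against exact zeros, which both lab reporting and the
plume simulator can produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ResponseTransform:
    """Monotone log transform ``z = log(y + offset)`` applied before fitting."""

    offset: float = 1.0

    def forward(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if np.any(y + self.offset <= 0):
            raise ValueError("transform undefined: y + offset must be positive")
        return np.log(y + self.offset)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(z, dtype=float)) - self.offset


@dataclass
class MonitoringDataset:
    """Long-format monitoring observations ``(well, s1, s2, t, y)``.

    ``y`` is the response on the transformed (model) scale; ``raw`` holds the
    original concentrations when available.  All arrays share one length.
    """

    well: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    t: np.ndarray
    y: np.ndarray
    raw: np.ndarray | None = None
    transform: ResponseTransform = field(default_factory=ResponseTransform)

    def __post_init__(self) -> None:
        self.well = np.asarray(self.well, dtype=object)
        for name in ("s1", "s2", "t", "y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(self.well), len(self.s1), len(self.s2), len(self.t), len(self.y)}
        if lengths != {len(self.well)}:
            raise ValueError(f"field lengths differ: {sorted(lengths)}")
        if len(self.well) == 0:
            raise ValueError("empty dataset")
        for name in ("s1", "s2", "t", "y"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in '{name}'")
        if self.raw is not None:
            self.raw = np.asarray(self.raw, dtype=float)
            if len(self.raw) != len(self.well):
                raise ValueError("raw length mismatch")

    @classmethod
    def from_raw(
        cls,
        well,
        s1,
        s2,
        t,
        raw,
        transform: ResponseTransform | None = None,
    ) -> "MonitoringDataset":
        """Build a dataset from raw concentrations, applying the transform."""
        transform = transform or ResponseTransform()
        raw = np.asarray(raw, dtype=float)
        return cls(
            well=np.asarray(well, dtype=object),
            s1=s1,
            s2=s2,
            t=t,
            y=transform.forward(raw),
            raw=raw,
            transform=transform,
        )

    @property
    def n(self) -> int:
        return len(self.well)

    @property
    def wells(self) -> np.ndarray:
        """Unique well identifiers in order of first appearance."""
        _, idx = np.unique(self.well.astype(str), return_index=True)
        return self.well[np.sort(idx)]

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def well_coordinates(self) -> np.ndarray:
        """(n_wells, 2) array of per-well (s1, s2), first occurrence wins."""
        coords = []
        seen = set()
        for i, w in enumerate(self.well):
            if w not in seen:
                seen.add(w)
                coords.append((self.s1[i], self.s2[i]))
        return np.asarray(coords, dtype=float)

    def subset(self, mask_or_index) -> "MonitoringDataset":
        idx = np.asarray(mask_or_index)
        return MonitoringDataset(
            well=self.well[idx],
            s1=self.s1[idx],
            s2=self.s2[idx],
            t=self.t[idx],
            y=self.y[idx],
            raw=None if self.raw is None else self.raw[idx],
            transform=self.transform,
        )

    def drop_wells(self, wells_to_drop) -> "MonitoringDataset":
        drop = {str(w) for w in np.atleast_1d(np.asarray(wells_to_drop, dtype=object))}
        keep = np.array([str(w) not in drop for w in self.well])
        if not keep.any():
            raise ValueError("dropping these wells would empty the dataset")
        return self.subset(keep)

    def checksum(self) -> str:
        """Stable content hash; used to assert dataset sharing across selectors."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.asarray([str(w) for w in self.well], dtype="U64").tobytes())
        for a in (self.s1, self.s2, self.t, self.y):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()
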