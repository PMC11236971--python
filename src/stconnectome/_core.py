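"""Shared domain objects: functional-system vocabulary, parcellation labels,
and the structural connectivity template.

The analysis labels every grey-matter region with one of eight large-scale
functional systems: the seven canonical resting-state systems (visual,
somatomotor, dorsal attention, ventral attention, limbic, frontoparietal,
default mode) plus the cerebellar system.  A single structural connectome
matrix — streamline counts between region pairs, shared by every subject in
a study — constrains which co-activations can form edges downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical ordering of the eight functional systems.
SYSTEMS = ("VIS", "SM", "DA", "VA", "LIM", "FP", "DM", "CBL")
SYSTEM_INDEX = {name: i for i, name in enumerate(SYSTEMS)}
N_SYSTEMS = len(SYSTEMS)


class DimensionError(ValueError):
    """Inputs have inconsistent or invalid shapes."""


class ValidationError(ValueError):
    """Inputs violate a documented contract (values, vocabulary, finiteness)."""


class InsufficientDataError(ValueError):
    """A metric's precondition (enough components / regions) is not met."""


@dataclass(frozen=True)
class Parcellation:
    """Region label table: one functional system per region.

    Parameters
    ----------
    region_names
        Length-N array of region name strings.
    systems
        Length-N array of system labels, each one of :data:`SYSTEMS`.
        Region ids are the implicit contiguous indices ``0..N-1``.
    """

    region_names: np.ndarray
    systems: np.ndarray

    def __post_init__(self) -> None:
        names = np.asarray(self.region_names, dtype=object)
        systems = np.asarray(self.systems, dtype=object)
        if names.ndim != 1 or systems.ndim != 1 or names.size != systems.size:
            raise DimensionError(
                "region_names and systems must be 1-D and equal length"
            )
        unknown = sorted({s for s in systems if s not in SYSTEM_INDEX})
        if unknown:
            raise ValidationError(
                f"unknown system labels {unknown}; valid names are {list(SYSTEMS)}"
            )
        object.__setattr__(self, "region_names", names)
        object.__setattr__(self, "systems", systems)
        idx = np.array([SYSTEM_INDEX[s] for s in systems], dtype=np.int64)
        object.__setattr__(self, "_system_idx", idx)

    @property
    def n_regions(self) -> int:
        return int(self.systems.size)

    @property
    def system_idx(self) -> np.ndarray:
        """Length-N integer codes into :data:`SYSTEMS`."""
        return self._system_idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.arange(self.n_regions, dtype=int),
                "region_name": self.region_names,
                "system": self.systems,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        required = {"region_id", "region_name", "system"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"label table missing columns {sorted(missing)}")
        ids = df["region_id"].to_numpy()
        if ids.size and (np.unique(ids).size != ids.size):
            raise ValidationError("duplicate region ids in label table")
        order = np.argsort(ids)
        ids = ids[order]
        if ids.size and not np.array_equal(ids, np.arange(ids.size)):
            raise ValidationError("region ids must be contiguous 0..N-1")
        return cls(
            region_names=df["region_name"].to_numpy()[order],
            systems=df["system"].to_numpy()[order],
        )


@dataclass(frozen=True)
class StructuralConnectome:
    """Structural connectivity template (streamline-count semantics).

    ``weights`` is an N x N symmetric nonnegative matrix with zero diagonal.
    The graph stage consumes a *binarized* view: an edge is present between
    regions i and j iff ``weights[i, j] > sc_threshold``.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionError("structural matrix must be square")
        if not np.all(np.isfinite(w)):
            raise ValidationError("structural matrix contains non-finite values")
        if np.any(w < 0):
            raise ValidationError("structural weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ValidationError("structural matrix must be symmetric")
        w = 0.5 * (w + w.T)  # exact symmetry after float round-trips
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return int(self.weights.shape[0])

    def binarized(self, sc_threshold: float = 0.0) -> np.ndarray:
        """Boolean adjacency: edge iff weight strictly above ``sc_threshold``."""
        return self.weights > sc_threshold

    def edge_list(self, sc_threshold: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangular endpoints (i < j) of the binarized graph."""
        i, j = np.nonzero(np.triu(self.binarized(sc_threshold), k=1))
        return i, j
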