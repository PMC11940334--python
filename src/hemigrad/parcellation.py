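"""Homotopic parcellation table.

A homotopic parcellation pairs every left-hemisphere region with a mirrored
right-hemisphere partner and assigns both to the same functional network.
Downstream, hemispheric asymmetry indices are differences of gradient scores
across these pairs, so the pairing must be a hemisphere-crossing involution
and network labels must agree within each pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Canonical ordering of the seven resting-state networks.
CANONICAL_NETWORKS = ("VIS", "SMN", "DAN", "VAN", "LIM", "CON", "DMN")


@dataclass
class ParcellationInfo:
    """Region table: id, hemisphere, homotopic partner, network label.

    Regions are stored in file order; ``region_id`` is the 0-based internal
    id (files may be 1-based, see :func:`read_parcellation`).
    """

    region_id: np.ndarray
    hemisphere: np.ndarray
    partner_id: np.ndarray
    network: np.ndarray

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.partner_id = np.asarray(self.partner_id, dtype=int)
        self.network = np.asarray(self.network, dtype=object)
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    @property
    def left_indices(self) -> np.ndarray:
        """Positions (row indices) of left-hemisphere regions, file order."""
        return np.flatnonzero(self.hemisphere == "L")

    @property
    def right_indices(self) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == "R")

    @property
    def networks(self) -> list[str]:
        """Present network labels in canonical order (extras appended)."""
        present = set(self.network.tolist())
        ordered = [n for n in CANONICAL_NETWORKS if n in present]
        ordered += sorted(present - set(ordered))
        return ordered

    def index_of(self, region_id: int) -> int:
        pos = np.flatnonzero(self.region_id == region_id)
        if len(pos) != 1:
            raise DataError(f"region id {region_id} not found (or duplicated)")
        return int(pos[0])

    def partner_index(self, pos: int) -> int:
        """Row position of the homotopic partner of the region at row `pos`."""
        return self.index_of(self.partner_id[pos])

    def network_mask(self, network: str, hemisphere: str | None = None) -> np.ndarray:
        mask = self.network == network
        if hemisphere is not None:
            mask &= self.hemisphere == hemisphere
        return mask

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n = self.n_regions
        if len(set(self.region_id.tolist())) != n:
            raise DataError("region ids are not unique")
        if not set(self.hemisphere.tolist()) <= {"L", "R"}:
            raise DataError("hemisphere labels must be 'L' or 'R'")
        n_left = int((self.hemisphere == "L").sum())
        if n_left * 2 != n:
            raise DataError(
                f"unequal hemisphere sizes: {n_left} left vs {n - n_left} right"
            )
        id_to_pos = {int(r): i for i, r in enumerate(self.region_id)}
        for i in range(n):
            j = id_to_pos.get(int(self.partner_id[i]))
            if j is None:
                raise DataError(f"partner id {self.partner_id[i]} of region "
                                f"{self.region_id[i]} not in table")
            if self.hemisphere[i] == self.hemisphere[j]:
                raise DataError(f"homotopic partner of region {self.region_id[i]} "
                                "lies in the same hemisphere")
            if int(self.partner_id[j]) != int(self.region_id[i]):
                raise DataError("partner mapping is not an involution "
                                f"(region {self.region_id[i]})")
            if self.network[i] != self.network[j]:
                raise DataError(f"homotopic pair ({self.region_id[i]}, "
                                f"{self.region_id[j]}) has mismatched networks")

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_id,
                "hemisphere": self.hemisphere,
                "partner_id": self.partner_id,
                "network": self.network,
            }
        )


@dataclass
class HomotopicPairs:
    """Left-region-indexed view of the homotopic pairing.

    ``left_pos[k]`` / ``right_pos[k]`` are row positions of pair ``k`` in the
    full region table; ``left_local[k]`` / ``right_local[k]`` are positions
    within each hemisphere's own ordering (as used by hemispheric blocks).
    """

    left_ids: np.ndarray
    left_pos: np.ndarray
    right_pos: np.ndarray
    left_local: np.ndarray
    right_local: np.ndarray
    network: np.ndarray = field(default=None)


def homotopic_pairs(parcellation: ParcellationInfo) -> HomotopicPairs:
    left = parcellation.left_indices
    right = parcellation.right_indices
    right_local_of_pos = {int(p): k for k, p in enumerate(right)}
    right_pos = np.array([parcellation.partner_index(int(p)) for p in left])
    return HomotopicPairs(
        left_ids=parcellation.region_id[left],
        left_pos=left,
        right_pos=right_pos,
        left_local=np.arange(len(left)),
        right_local=np.array([right_local_of_pos[int(p)] for p in right_pos]),
        network=parcellation.network[left],
    )
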