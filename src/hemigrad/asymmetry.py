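"""Hemispheric asymmetry indices of gradient scores.

The asymmetry index (AI) of a homotopic pair is the left-minus-right
difference of aligned gradient scores: intra AI uses the within-hemisphere
gradients (LL - RR), inter AI the cross-hemisphere ones (LR - RL).  Positive
AI means leftward asymmetry.  Network-level AI averages each hemisphere's
scores over a network's regions first and then differences the means (which,
for a homotopic parcellation, equals the mean of the pair-level AIs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, StateError
from .gradients import SubjectGradients
from .parcellation import ParcellationInfo, homotopic_pairs

AI_TYPES = ("intra", "inter")
DEFAULT_N_GRADIENTS = 3


@dataclass
class AsymmetryMap:
    """Pair-level AI values: (homotopic pair x gradient x {intra, inter}).

    Pairs are indexed by their left-hemisphere region id.
    """

    values: np.ndarray                 # (n_pairs, n_gradients, 2)
    pair_left_ids: np.ndarray
    networks: np.ndarray

    def ai(self, gradient: int, kind: str) -> np.ndarray:
        """AI vector over pairs for a 1-based gradient and type."""
        return self.values[:, gradient - 1, AI_TYPES.index(kind)]

    def to_series(self) -> pd.Series:
        """Flatten to a feature row: G{g}_{type}_pair_{leftRegionId}."""
        data = {}
        for g in range(self.values.shape[1]):
            for t, kind in enumerate(AI_TYPES):
                for p, left_id in enumerate(self.pair_left_ids):
                    data[f"G{g + 1}_{kind}_pair_{left_id}"] = self.values[p, g, t]
        return pd.Series(data)


@dataclass
class NetworkAI:
    """Network-level AI values: (network x gradient x {intra, inter})."""

    values: np.ndarray                 # (n_networks, n_gradients, 2)
    networks: list[str]

    def ai(self, network: str, gradient: int, kind: str) -> float:
        return float(self.values[self.networks.index(network),
                                 gradient - 1, AI_TYPES.index(kind)])

    def to_series(self) -> pd.Series:
        data = {}
        for g in range(self.values.shape[1]):
            for t, kind in enumerate(AI_TYPES):
                for k, net in enumerate(self.networks):
                    data[f"G{g + 1}_{kind}_net_{net}"] = self.values[k, g, t]
        return pd.Series(data)


def _check_aligned(grads: SubjectGradients) -> None:
    for g in grads:
        if not g.aligned:
            raise StateError(
                f"gradient set {g.source!r} is not aligned to a template; "
                "run procrustes_align first"
            )


def compute_ai(
    grads: SubjectGradients,
    parcellation: ParcellationInfo,
    n_gradients: int = DEFAULT_N_GRADIENTS,
) -> AsymmetryMap:
    """Pair-level asymmetry indices from a subject's four aligned gradients.

    intra AI(pair, g) = LL score of the left region - RR score of its
    partner; inter AI(pair, g) = LR score - RL score of the partner.
    """
    _check_aligned(grads)
    pairs = homotopic_pairs(parcellation)
    if grads.LL.n_components < n_gradients:
        raise DataError(f"need >= {n_gradients} components, "
                        f"got {grads.LL.n_components}")
    n_pairs = len(pairs.left_ids)
    values = np.empty((n_pairs, n_gradients, 2))
    for g in range(n_gradients):
        values[:, g, 0] = (grads.LL.coordinates[pairs.left_local, g]
                           - grads.RR.coordinates[pairs.right_local, g])
        values[:, g, 1] = (grads.LR.coordinates[pairs.left_local, g]
                           - grads.RL.coordinates[pairs.right_local, g])
    if not np.all(np.isfinite(values)):
        raise DataError("non-finite AI values")
    return AsymmetryMap(values=values, pair_left_ids=pairs.left_ids,
                        networks=pairs.network)


def network_ai(
    grads: SubjectGradients,
    parcellation: ParcellationInfo,
    n_gradients: int = DEFAULT_N_GRADIENTS,
) -> NetworkAI:
    """Network-level AI: hemisphere means over network regions, then L - R."""
    _check_aligned(grads)
    nets = parcellation.networks
    left_nets = parcellation.network[parcellation.left_indices]
    right_nets = parcellation.network[parcellation.right_indices]
    values = np.empty((len(nets), n_gradients, 2))
    for k, net in enumerate(nets):
        lmask = left_nets == net
        rmask = right_nets == net
        if not lmask.any() or not rmask.any():
            raise DataError(f"network {net!r} is empty in one hemisphere")
        for g in range(n_gradients):
            values[k, g, 0] = (grads.LL.coordinates[lmask, g].mean()
                               - grads.RR.coordinates[rmask, g].mean())
            values[k, g, 1] = (grads.LR.coordinates[lmask, g].mean()
                               - grads.RL.coordinates[rmask, g].mean())
    return NetworkAI(values=values, networks=list(nets))


def cohort_ai_table(
    subject_maps: dict[str, AsymmetryMap | NetworkAI],
) -> pd.DataFrame:
    """Stack per-subject AI maps into a subject x feature table."""
    rows = {sid: m.to_series() for sid, m in subject_maps.items()}
    df = pd.DataFrame(rows).T
    df.index.name = "subject_id"
    return df


def parse_feature_name(name: str) -> tuple[int, str, str, str]:
    """Split 'G1_intra_net_DAN' -> (1, 'intra', 'net', 'DAN')."""
    g, kind, level, label = name.split("_", 3)
    return int(g[1:]), kind, level, label
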