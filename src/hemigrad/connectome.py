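"""Functional connectivity construction and hemispheric decomposition.

From a (regions x timepoints) series we build a Fisher-z FC matrix
(``z = atanh(Pearson r)``, diagonal set to 0) and split it into the four
hemispheric blocks: within-left (LL), within-right (RR), left-to-right (LR)
and right-to-left (RL).  Subject-level motion QC (framewise displacement
thresholds) also lives here, since it decides whose FC is computed at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError
from .parcellation import ParcellationInfo
from .simulate import SubjectRecord

#: subjects with mean FD above this (mm) are excluded
MEAN_FD_MAX = 0.35
#: subjects with any-frame FD above this (mm) are excluded
MAX_FD_MAX = 3.0


@dataclass
class Exclusion:
    subject_id: str
    reason: str


def qc_filter(
    subjects: list[SubjectRecord],
    mean_fd_max: float = MEAN_FD_MAX,
    max_fd_max: float = MAX_FD_MAX,
    exclude_missing_fd: bool = True,
) -> tuple[list[SubjectRecord], list[Exclusion]]:
    """Motion QC: drop subjects with mean FD > 0.35 mm or max FD > 3 mm.

    The rule is strict ``>``: boundary values are retained.  Returns the
    retained list and an exclusion log with one reason per dropped subject.
    """
    kept: list[SubjectRecord] = []
    log: list[Exclusion] = []
    for s in subjects:
        if s.mean_fd is None or s.max_fd is None or np.isnan(s.mean_fd) or np.isnan(s.max_fd):
            if exclude_missing_fd:
                log.append(Exclusion(s.subject_id, "missing FD"))
                continue
            kept.append(s)
            continue
        if s.mean_fd > mean_fd_max:
            log.append(Exclusion(s.subject_id, f"mean FD {s.mean_fd:.3f} > {mean_fd_max}"))
        elif s.max_fd > max_fd_max:
            log.append(Exclusion(s.subject_id, f"max FD {s.max_fd:.3f} > {max_fd_max}"))
        else:
            kept.append(s)
    return kept, log


def compute_fc(ts: np.ndarray) -> np.ndarray:
    """Fisher-z FC matrix of a (regions x timepoints) series.

    Off-diagonal entries are atanh of the Pearson correlation; the diagonal
    is set to 0 (atanh(1) is undefined and self-connectivity carries no
    information).  Constant rows and perfectly correlated region pairs are
    data errors, reported with the offending region index.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise DataError(f"time series must be 2-D, got shape {ts.shape}")
    n, t = ts.shape
    if t < 3:
        raise DataError(f"need >= 3 timepoints, got {t}")
    if not np.all(np.isfinite(ts)):
        raise DataError("time series contain non-finite values")
    sd = ts.std(axis=1)
    # scale-aware zero test: exact-constant rows leave rounding residue
    bad = np.flatnonzero(sd <= 1e-12 * (np.abs(ts).max(axis=1) + 1.0))
    if bad.size:
        raise DataError(f"constant time series for region(s) {bad.tolist()}")
    r = np.corrcoef(ts)
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0 - 1e-15):
        i, j = np.argwhere((np.abs(r) >= 1.0 - 1e-15) & off)[0]
        raise DataError(f"|r| = 1 between regions {i} and {j}; "
                        "Fisher z is undefined (duplicated signal?)")
    z = np.arctanh(r, where=off, out=np.zeros_like(r))
    np.fill_diagonal(z, 0.0)
    return 0.5 * (z + z.T)


@dataclass
class HemisphericBlocks:
    """The four hemispheric FC blocks of one subject.

    Rows of LL and LR are left-hemisphere regions; rows of RR and RL are
    right-hemisphere regions.  ``left_ids`` / ``right_ids`` give the region
    ids of the block rows, in within-hemisphere order.
    """

    LL: np.ndarray
    RR: np.ndarray
    LR: np.ndarray
    RL: np.ndarray
    left_ids: np.ndarray = field(default=None)
    right_ids: np.ndarray = field(default=None)

    def block(self, name: str) -> np.ndarray:
        return getattr(self, name)


def split_hemispheric(
    fc: np.ndarray, parcellation: ParcellationInfo
) -> HemisphericBlocks:
    """Split an FC matrix into LL, RR, LR and RL blocks.

    Region order inside each hemisphere follows the parcellation file order;
    by construction RL equals LR transposed (they diverge downstream, where
    gradients are computed over each block's own row profiles).
    """
    fc = np.asarray(fc, dtype=float)
    if fc.shape[0] != fc.shape[1] or fc.shape[0] != parcellation.n_regions:
        raise DataError(
            f"FC shape {fc.shape} does not match parcellation "
            f"({parcellation.n_regions} regions)"
        )
    li = parcellation.left_indices
    ri = parcellation.right_indices
    if len(li) != len(ri):
        raise DataError("unequal hemisphere region counts")
    return HemisphericBlocks(
        LL=fc[np.ix_(li, li)],
        RR=fc[np.ix_(ri, ri)],
        LR=fc[np.ix_(li, ri)],
        RL=fc[np.ix_(ri, li)],
        left_ids=parcellation.region_id[li],
        right_ids=parcellation.region_id[ri],
    )


def reassemble(blocks: HemisphericBlocks, parcellation: ParcellationInfo) -> np.ndarray:
    """Inverse of :func:`split_hemispheric` (round-trip check helper)."""
    n = parcellation.n_regions
    fc = np.empty((n, n))
    li, ri = parcellation.left_indices, parcellation.right_indices
    fc[np.ix_(li, li)] = blocks.LL
    fc[np.ix_(ri, ri)] = blocks.RR
    fc[np.ix_(li, ri)] = blocks.LR
    fc[np.ix_(ri, li)] = blocks.RL
    return fc
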