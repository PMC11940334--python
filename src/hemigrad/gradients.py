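"""Functional gradients: thresholding, normalized-angle affinity, diffusion
map embedding, templates and Procrustes alignment.

The embedding follows the standard connectome-gradient recipe: each
hemispheric FC block is sparsified to its strongest connections (top 10% of
each region's profile), converted to a normalized-angle affinity matrix, and
embedded with diffusion maps (anisotropy alpha = 0.5, diffusion time t = 0).
Group templates are embedded from group-average blocks, and individual
gradient sets are aligned to them by orthogonal Procrustes rotation so that
component order, sign, and frame are comparable across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._utils import check_symmetric
from .connectome import HemisphericBlocks
from .exceptions import DataError, NumericalError, ParameterError

DEFAULT_DENSITY = 0.10
DEFAULT_ALPHA = 0.5
DEFAULT_DIFFUSION_TIME = 0.0
DEFAULT_N_COMPONENTS = 10


@dataclass
class GradientSet:
    """Embedding coordinates of one block's regions.

    ``coordinates`` is (regions x k) with columns ordered by descending
    non-trivial eigenvalue.  ``explained_variance`` is lambda_i over the sum
    of the retained non-trivial eigenvalues (an alternative lambda^2-based
    definition is available through :func:`diffusion_map`).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    source: str = ""              # LL / RR / LR / RL / intra / inter
    aligned: bool = False
    region_ids: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class GradientTemplate:
    """Group-level gradient frame individuals are aligned to."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    provenance: str = ""          # "intra" or "inter"
    reference: str = ""
    region_ids: np.ndarray | None = None


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def threshold_profiles(
    block: np.ndarray,
    density: float = DEFAULT_DENSITY,
    exclude_diagonal: bool | None = None,
) -> np.ndarray:
    """Keep the top-``density`` fraction of each row profile, zero the rest.

    Entries are ranked by signed value; ceil(density * n) survive per row.
    Ties at the cut are broken toward the smallest column index, making the
    operation bit-reproducible.  For square blocks the diagonal is never
    selected (it is 0 by FC construction and carries no information); pass
    ``exclude_diagonal=False`` to override.
    """
    if not 0 < density <= 1:
        raise ParameterError(f"density must be in (0, 1], got {density}")
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:  # a single profile
        return threshold_profiles(block[None, :], density, exclude_diagonal=False)[0]
    if block.ndim != 2:
        raise DataError("block must be a 1-D profile or 2-D matrix")
    n_rows, n_cols = block.shape
    if density == 1.0:
        return block.copy()
    if exclude_diagonal is None:
        exclude_diagonal = n_rows == n_cols
    k = int(np.ceil(density * n_cols))
    ranked = block.copy()
    if exclude_diagonal and n_rows == n_cols:
        np.fill_diagonal(ranked, -np.inf)
    finite = np.where(np.isfinite(ranked), ranked, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        flat_rows = (np.nanmax(finite, axis=1) - np.nanmin(finite, axis=1)) == 0
    if np.any(flat_rows):
        warnings.warn(
            f"all-equal profile(s) at row(s) {np.flatnonzero(flat_rows).tolist()}; "
            f"keeping the first {k} entries", stacklevel=2,
        )
    # stable argsort of the negated values -> ties resolve to smallest index
    order = np.argsort(-ranked, axis=1, kind="stable")[:, :k]
    out = np.zeros_like(block)
    rows = np.repeat(np.arange(n_rows), k)
    out[rows, order.ravel()] = block[rows, order.ravel()]
    return out


# ---------------------------------------------------------------------------
# affinity
# ---------------------------------------------------------------------------

def normalized_angle_affinity(sparse_block: np.ndarray) -> np.ndarray:
    """Normalized-angle similarity between row profiles.

    For profiles u, v with cosine similarity c (clipped to [-1, 1]) the
    affinity is ``1 - arccos(c) / pi``: 1 for identical directions, 0.5 for
    orthogonal ones, 0 for antipodal ones.  Result is symmetric with unit
    diagonal and entries in [0, 1].
    """
    X = np.asarray(sparse_block, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise DataError(f"zero-norm profile(s) at row(s) {bad.tolist()}")
    U = X / norms[:, None]
    c = np.clip(U @ U.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(c) / np.pi
    aff = 0.5 * (aff + aff.T)
    np.fill_diagonal(aff, 1.0)
    return aff


# ---------------------------------------------------------------------------
# diffusion map embedding
# ---------------------------------------------------------------------------

def diffusion_map(
    affinity: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    diffusion_time: float = DEFAULT_DIFFUSION_TIME,
    n_components: int = DEFAULT_N_COMPONENTS,
    ev_mode: str = "lambda",
    source: str = "",
    region_ids: np.ndarray | None = None,
) -> GradientSet:
    """Diffusion-map embedding of a symmetric affinity matrix.

    Procedure: (i) density-normalize ``W_a = D^-a W D^-a`` with D the
    row-sum diagonal; (ii) form the Markov operator ``P = D_a^-1 W_a``;
    (iii) eigendecompose (via the symmetric conjugate of P, solved densely
    and deterministically); (iv) drop the trivial constant eigenvector
    (lambda = 1) and scale component i by ``lambda_i / (1 - lambda_i)``
    when ``diffusion_time == 0`` (the reference-toolbox convention) or by
    ``lambda_i ** t`` otherwise; (v) report per-component explained
    variance as ``lambda_i / sum(lambda_j)`` over the retained non-trivial
    eigenvalues (``ev_mode="lambda_sq"`` uses squared eigenvalues).

    A second unit eigenvalue means the affinity graph is disconnected,
    which is an error: gradients are only meaningful on one component.
    """
    W = np.asarray(affinity, dtype=float)
    try:
        check_symmetric(W, tol=1e-8, name="affinity")
    except ValueError as exc:
        raise DataError(str(exc)) from None
    n = W.shape[0]
    if not (0 < n_components < n - 1):
        raise ParameterError(f"need 0 < n_components < n - 1 = {n - 1}")
    if W.min() < -1e-12 or W.max() > 1 + 1e-12:
        raise DataError("affinity entries must lie in [0, 1]")

    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise DataError("affinity has a zero-degree node")
    d_alpha_pow = d ** (-float(alpha))
    W_a = W * np.outer(d_alpha_pow, d_alpha_pow)
    d_a = W_a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d_a)
    S = W_a * np.outer(inv_sqrt, inv_sqrt)      # symmetric conjugate of P
    S = 0.5 * (S + S.T)
    try:
        evals, evecs = np.linalg.eigh(S)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"eigensolver failed: {exc}") from None
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n > 2 and evals[1] >= 1.0 - 1e-10:
        raise DataError(
            "affinity graph is disconnected (unit eigenvalue has multiplicity > 1)"
        )
    # right eigenvectors of P, normalized so the trivial one is all-ones
    V = evecs * inv_sqrt[:, None]
    psi = V / V[:, [0]]
    lam = evals[1:n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam ** float(diffusion_time)
    coords = psi[:, 1:n_components + 1] * scale
    weights = lam**2 if ev_mode == "lambda_sq" else lam
    ev = weights / weights.sum()
    return GradientSet(
        coordinates=coords, eigenvalues=lam, explained_variance=ev,
        source=source, aligned=False, region_ids=region_ids,
    )


def embed_block(
    block: np.ndarray,
    density: float = DEFAULT_DENSITY,
    alpha: float = DEFAULT_ALPHA,
    diffusion_time: float = DEFAULT_DIFFUSION_TIME,
    n_components: int = DEFAULT_N_COMPONENTS,
    source: str = "",
    region_ids: np.ndarray | None = None,
) -> GradientSet:
    """threshold -> normalized-angle affinity -> diffusion map, in one call."""
    sparse = threshold_profiles(block, density)
    aff = normalized_angle_affinity(sparse)
    return diffusion_map(aff, alpha, diffusion_time, n_components,
                         source=source, region_ids=region_ids)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _orient_columns(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip columns so each correlates positively with its reference vector.

    ``reference`` may be a single vector (applied to every column) or a
    (n x m) matrix whose column ``min(i, m-1)`` orients component ``i``.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.ndim == 1:
        ref = ref[:, None]
    out = coords.copy()
    for i in range(out.shape[1]):
        r = ref[:, min(i, ref.shape[1] - 1)]
        c = np.corrcoef(out[:, i], r)[0, 1]
        if np.isfinite(c) and c < 0:
            out[:, i] = -out[:, i]
    return out


def build_templates(
    blocks_list: list[HemisphericBlocks],
    density: float = DEFAULT_DENSITY,
    alpha: float = DEFAULT_ALPHA,
    diffusion_time: float = DEFAULT_DIFFUSION_TIME,
    n_components: int = DEFAULT_N_COMPONENTS,
    sign_reference: np.ndarray | None = None,
    reference_label: str = "",
) -> tuple[GradientTemplate, GradientTemplate]:
    """Build intra- and inter-hemispheric gradient templates.

    The intra template embeds the element-wise mean of all reference
    subjects' LL and RR blocks; the inter template the mean of their LR and
    RL blocks.  Template column signs are fixed by positive correlation with
    ``sign_reference`` (default: the indicator of the first half of regions;
    for synthetic studies pass the planted loadings so component i is
    oriented along planted axis i).
    """
    if not blocks_list:
        raise DataError("need at least one reference subject")
    shape = blocks_list[0].LL.shape
    for b in blocks_list:
        if b.LL.shape != shape or b.RR.shape != shape or b.LR.shape != shape:
            raise DataError("block shapes differ across reference subjects")
    mean_intra = np.mean([np.stack([b.LL, b.RR]).mean(0) for b in blocks_list], axis=0)
    mean_inter = np.mean([np.stack([b.LR, b.RL]).mean(0) for b in blocks_list], axis=0)
    n = shape[0]
    if sign_reference is None:
        sign_reference = (np.arange(n) < n // 2).astype(float)
    templates = []
    for name, mat in (("intra", mean_intra), ("inter", mean_inter)):
        g = embed_block(mat, density, alpha, diffusion_time, n_components, source=name)
        coords = _orient_columns(g.coordinates, sign_reference)
        templates.append(GradientTemplate(
            coordinates=coords, eigenvalues=g.eigenvalues,
            explained_variance=g.explained_variance, provenance=name,
            reference=reference_label, region_ids=blocks_list[0].left_ids,
        ))
    return templates[0], templates[1]


# ---------------------------------------------------------------------------
# Procrustes alignment
# ---------------------------------------------------------------------------

def procrustes_align(g: GradientSet, template: GradientTemplate) -> GradientSet:
    """Align a gradient set to a template by orthogonal Procrustes rotation.

    Solves ``R = argmin || G R - T ||_F`` over orthogonal R via the SVD of
    ``G^T T`` (no centering, no scaling) and returns ``G R`` with the
    alignment tag set.  A rank-deficient cross-product triggers a warning;
    the rotation is still the deterministic SVD solution, arbitrary only in
    the degenerate subspace.
    """
    G = g.coordinates
    T = template.coordinates
    if G.shape != T.shape:
        raise DataError(f"shape mismatch: gradients {G.shape} vs template {T.shape}")
    M = G.T @ T
    U, s, Vt = np.linalg.svd(M)
    if np.any(s < 1e-12 * max(s.max(), 1.0)):
        warnings.warn("rank-deficient cross-product in Procrustes alignment; "
                      "rotation fixed only on the non-degenerate subspace",
                      stacklevel=2)
    R = U @ Vt
    return replace(g, coordinates=G @ R, aligned=True)


# ---------------------------------------------------------------------------
# per-subject convenience
# ---------------------------------------------------------------------------

@dataclass
class SubjectGradients:
    """The four aligned gradient sets of one subject."""

    LL: GradientSet
    RR: GradientSet
    LR: GradientSet
    RL: GradientSet
    subject_id: str = ""

    def __iter__(self):
        yield from (self.LL, self.RR, self.LR, self.RL)


def subject_gradients(
    blocks: HemisphericBlocks,
    intra_template: GradientTemplate,
    inter_template: GradientTemplate,
    density: float = DEFAULT_DENSITY,
    alpha: float = DEFAULT_ALPHA,
    diffusion_time: float = DEFAULT_DIFFUSION_TIME,
    n_components: int = DEFAULT_N_COMPONENTS,
    subject_id: str = "",
) -> SubjectGradients:
    """Embed and align all four hemispheric blocks of one subject.

    LL and RR align to the intra-hemispheric template; LR and RL to the
    inter-hemispheric one.  Rows of LL/LR are left regions, rows of RR/RL
    right regions (each block yields gradients for its source hemisphere).
    """
    out = {}
    for name, template in (("LL", intra_template), ("RR", intra_template),
                           ("LR", inter_template), ("RL", inter_template)):
        ids = blocks.left_ids if name in ("LL", "LR") else blocks.right_ids
        g = embed_block(blocks.block(name), density, alpha, diffusion_time,
                        n_components, source=name, region_ids=ids)
        out[name] = procrustes_align(g, template)
    return SubjectGradients(subject_id=subject_id, **out)
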