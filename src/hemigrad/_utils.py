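"""Shared helpers: deterministic RNG derivation and small validators."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def subject_seed_sequence(seed: int, subject_id: str) -> np.random.SeedSequence:
    """Derive a per-subject random stream from (study seed, subject id).

    Uses CRC32 of the id so the mapping is stable across platforms and
    Python hash randomization.
    """
    return np.random.SeedSequence([int(seed) & MAX_SEED, zlib.crc32(subject_id.encode())])


def rng_for_subject(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(subject_seed_sequence(seed, subject_id))


def check_square(mat: np.ndarray, name: str = "matrix") -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")


def check_symmetric(mat: np.ndarray, tol: float = 1e-10, name: str = "matrix") -> None:
    check_square(mat, name)
    if not np.allclose(mat, mat.T, atol=tol):
        raise ValueError(f"{name} is not symmetric within {tol}")
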