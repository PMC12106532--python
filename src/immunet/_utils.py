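"""Shared helpers: seeding, validation, small numerics."""

from __future__ import annotations

import hashlib

import numpy as np

#: Stage order of the full pipeline; child seeds are derived in this order.
STAGES = (
    "simulate",
    "preprocess",
    "cluster",
    "embed",
    "diffabund",
    "network",
    "classify",
    "report",
)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, a Generator, or None into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one child seed per pipeline stage from a single master seed.

    Uses numpy's SeedSequence spawning so stages are statistically
    independent and the whole run is reproducible from one integer.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1, np.uint32)[0])
        for stage, child in zip(STAGES, children)
    }


def check_psd(matrix: np.ndarray, name: str = "covariance", tol: float = 1e-8) -> None:
    """Raise ValueError unless *matrix* is symmetric positive semi-definite."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{name} must be square, got shape {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(matrix)
    if eigvals.min() < -tol * max(1.0, eigvals.max()):
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
        )


def closure(logratios: np.ndarray) -> np.ndarray:
    """Map log-ratio vectors to compositions on the simplex (softmax rows)."""
    z = np.asarray(logratios, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    expz = np.exp(z)
    return expz / expz.sum(axis=-1, keepdims=True)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
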