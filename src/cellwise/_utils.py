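"""Small shared helpers: compositional transforms, seeding, validation."""

from __future__ import annotations

import numpy as np

#: The five major brain cell types handled throughout the package, in canonical order.
CELL_TYPES = ("neuron", "astrocyte", "microglia", "oligodendrocyte", "endothelial")

#: Cell types counted as NeuN-negative in the neuron-vs-glia contrast.
NON_NEURONAL = tuple(ct for ct in CELL_TYPES if ct != "neuron")


def clr(p: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform of strictly positive compositions (rows)."""
    lp = np.log(p)
    return lp - lp.mean(axis=-1, keepdims=True)


def inv_clr(z: np.ndarray) -> np.ndarray:
    """Inverse centered log-ratio: softmax along the last axis."""
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one integer seed.

    Streams are drawn in a fixed order so that every run with the same master
    seed consumes identical randomness regardless of which stage runs first.
    """
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def check_probability_rows(p: np.ndarray, tol: float = 1e-9) -> None:
    if np.any(p < -tol):
        raise ValueError("proportions must be nonnegative")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=tol):
        raise ValueError("proportion rows must sum to 1")
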