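"""Shared helpers: deterministic RNG streams, sequence ops, multiple testing."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Independent generator keyed by (seed, stream-id).

    Adding new streams never perturbs draws of existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode("utf-8"))])
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    n = pm.size
    if n == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


def bonferroni_adjust(pvalues, n_tests: int | None = None) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if n_tests is None:
        n_tests = int(np.isfinite(p).sum())
    return np.minimum(p * max(n_tests, 1), 1.0)
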