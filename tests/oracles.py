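"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or fine sampling,
independent of the library's code paths.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def dice_brute_force(a: np.ndarray, b: np.ndarray) -> float:
    """Dice via explicit voxel-coordinate sets."""
    sa = {tuple(v) for v in np.argwhere(a)}
    sb = {tuple(v) for v in np.argwhere(b)}
    if not sa and not sb:
        return float("nan")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def density_brute_force(
    streamlines, affine: np.ndarray, shape, fine_step: float = 0.01
) -> np.ndarray:
    """Streamline visitation counts by fine point sampling.

    Walks every segment at ``fine_step`` mm, assigns each sample to the
    nearest voxel (ties toward the lower index) and counts each
    streamline at most once per voxel.
    """
    inv = np.linalg.inv(affine)
    counts = np.zeros(tuple(shape), dtype=int)
    for s in streamlines:
        visited = set()
        for p, q in zip(s[:-1], s[1:]):
            L = float(np.linalg.norm(q - p))
            n = max(int(np.ceil(L / fine_step)), 1)
            for t in np.linspace(0.0, 1.0, n + 1):
                x = p + t * (q - p)
                v = inv[:3, :3] @ x + inv[:3, 3]
                idx = tuple(int(np.ceil(c - 0.5)) for c in v)
                if all(0 <= idx[k] < shape[k] for k in range(3)):
                    visited.add(idx)
        for idx in visited:
            counts[idx] += 1
    return counts


def agreement_brute_force(pairs):
    """Per-voxel agree/disagree fractions by explicit looping."""
    shape = pairs[0][0].shape
    agree = np.zeros(shape)
    disagree = np.zeros(shape)
    for idx in np.ndindex(*shape):
        for a, b in pairs:
            if a[idx] and b[idx]:
                agree[idx] += 1
            elif bool(a[idx]) != bool(b[idx]):
                disagree[idx] += 1
    return agree / len(pairs), disagree / len(pairs)


def wilcoxon_exact_two_sided(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Zero differences are dropped; requires tie-free |d| for a clean
    null distribution.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s)
         for signs in itertools.product([0, 1], repeat=n)]
    )
    cdf = (ws <= w_obs + 1e-12).mean()
    sf = (ws >= w_obs - 1e-12).mean()
    return min(1.0, 2.0 * min(cdf, sf))


def closed_form_fa(evals) -> float:
    lam = np.asarray(evals, dtype=float)
    md = lam.mean()
    return float(np.sqrt(1.5 * ((lam - md) ** 2).sum() / (lam**2).sum()))
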