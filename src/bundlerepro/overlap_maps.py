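"""Spatial reproducibility: pairwise Dice overlap and voxelwise
agreement/disagreement maps.

Dice is the set-theoretic 2|A∩B|/(|A|+|B|) on binary voxel sets; the
agreement map gives, per voxel, the fraction of mask pairs in which both
masks contain the voxel (agreement) and in which exactly one does
(disagreement).  Fractions use the all-pairs denominator; the
pair-covers-voxel denominator is available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._grids import grids_close
from .voxelization import BundleMask


class GridAlignmentError(ValueError):
    """Masks compared on different grids."""


@dataclass
class DiceResult:
    dice: float
    vol_a: float
    vol_b: float
    intersection: float
    undefined: bool = False  # both masks empty: 0/0

    def __post_init__(self) -> None:
        if not self.undefined and not (0.0 <= self.dice <= 1.0 + 1e-12):
            raise ValueError(f"dice out of range: {self.dice}")


@dataclass
class AgreementMap:
    agree_frac: np.ndarray
    disagree_frac: np.ndarray
    n_pairs: int
    affine: np.ndarray

    @property
    def neither_frac(self) -> np.ndarray:
        return 1.0 - self.agree_frac - self.disagree_frac


def _check_aligned(a: BundleMask, b: BundleMask) -> None:
    if not grids_close(a.affine, a.mask.shape, b.affine, b.mask.shape):
        raise GridAlignmentError(
            f"mask grids differ: {a.mask.shape}@{a.voxel_sizes} vs "
            f"{b.mask.shape}@{b.voxel_sizes}"
        )


def dice(a: BundleMask, b: BundleMask) -> DiceResult:
    """Dice overlap of two binary masks on the same grid.

    A both-empty pair yields an ``undefined`` result (dice is NaN), not
    a zero: 0/0 carries no overlap information and is routed to QC.
    """
    _check_aligned(a, b)
    vox_mm3 = float(np.prod(a.voxel_sizes))
    na, nb = int(a.mask.sum()), int(b.mask.sum())
    ni = int((a.mask & b.mask).sum())
    if na + nb == 0:
        return DiceResult(float("nan"), 0.0, 0.0, 0.0, undefined=True)
    return DiceResult(
        dice=2.0 * ni / (na + nb),
        vol_a=na * vox_mm3,
        vol_b=nb * vox_mm3,
        intersection=ni * vox_mm3,
    )


def agreement_map(pairs: Sequence[tuple[BundleMask, BundleMask]]) -> AgreementMap:
    """Voxelwise agreement/disagreement fractions over mask pairs.

    All masks must live on one common grid (co-registration is assumed
    upstream).  ``agree_frac`` is the fraction of pairs where both masks
    contain the voxel; ``disagree_frac`` where exactly one does.
    """
    if len(pairs) == 0:
        raise ValueError("agreement_map requires at least one mask pair")
    ref_a, _ = pairs[0]
    agree = np.zeros(ref_a.mask.shape, dtype=np.float64)
    disagree = np.zeros(ref_a.mask.shape, dtype=np.float64)
    for a, b in pairs:
        _check_aligned(a, ref_a)
        _check_aligned(b, ref_a)
        both = a.mask & b.mask
        either = a.mask ^ b.mask
        agree += both
        disagree += either
    n = len(pairs)
    return AgreementMap(agree / n, disagree / n, n, np.asarray(ref_a.affine))
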