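"""Hemisphere-aware spherical spin permutations for parcellated maps.

The spin test generates spatial-autocorrelation-preserving null
permutations of a parcellated brain map: each permutation applies one
uniformly random 3-D rotation to the left hemisphere's parcel centroids
(and its x-mirrored twin to the right hemisphere), then reassigns each
parcel the identity of the nearest original centroid within its
hemisphere, greedily and one-to-one so every row is a genuine
permutation. Subcortical parcels have no spherical coordinates; they
receive an independent uniform shuffle among themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import rankdata

__all__ = ["SpinNull", "generate_spins", "spin_pvalue"]


@dataclass(frozen=True)
class SpinNull:
    """A bank of region-index permutations and the scope they cover."""

    permutations: np.ndarray  # (n_perm, n_regions) int
    region_ids: tuple[int, ...]
    seed: int
    # index groups that each permutation must map within (hemisphere closure)
    closed_groups: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        perms = np.asarray(self.permutations)
        n = len(self.region_ids)
        if perms.ndim != 2 or perms.shape[1] != n:
            raise ValueError("permutation table must be n_perm x n_regions")
        ref = np.arange(n)
        if not np.all(np.sort(perms, axis=1) == ref):
            raise ValueError("every spin row must be a permutation of the region indices")
        for group in self.closed_groups:
            g = np.asarray(group)
            if not np.all(np.isin(perms[:, g], g)):
                raise ValueError("spin rows must map each hemisphere/tissue group within itself")

    @property
    def n_perm(self) -> int:
        return self.permutations.shape[0]

    def to_files(self, tsv_path, json_path) -> None:
        import pandas as pd

        from .io import write_json, write_tsv

        write_tsv(pd.DataFrame(self.permutations), tsv_path)
        write_json(
            {"seed": self.seed, "n_perm": self.n_perm, "region_ids": list(self.region_ids)},
            json_path,
        )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))  # unique QR -> Haar on O(3)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]  # force a proper rotation
    return Q


def _greedy_assign(rotated: np.ndarray, original: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One-to-one nearest-centroid assignment, regions processed in random order."""
    n = rotated.shape[0]
    D = 1.0 - rotated @ original.T  # monotone in angular distance
    available = np.ones(n, dtype=bool)
    perm = np.empty(n, dtype=int)
    for i in rng.permutation(n):
        d = np.where(available, D[i], np.inf)
        j = int(np.argmin(d))
        perm[i] = j
        available[j] = False
    return perm


def generate_spins(atlas, n_perm: int = 1000, seed: int = 0, rotations=None) -> SpinNull:
    """Build a SpinNull for an atlas (or any subset of one).

    ``rotations`` is a testing hook: an iterable of explicit 3x3 rotation
    matrices used in place of random draws (e.g. the identity, which must
    yield the identity permutation on cortical indices).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    table = atlas.table
    cort = {
        side: np.flatnonzero((table["tissue_class"] == "cortical") & (table["hemisphere"] == side))
        for side in ("left", "right")
    }
    subcort = np.flatnonzero(table["tissue_class"] == "subcortical")
    coords = atlas.centroids()
    for side, idx in cort.items():
        if idx.size and not np.all(np.isfinite(coords[idx])):
            raise ValueError(f"{side} cortical regions are missing centroids")

    mirror = np.diag([-1.0, 1.0, 1.0])
    n = atlas.n_regions
    perms = np.empty((n_perm, n), dtype=int)
    rot_iter = iter(rotations) if rotations is not None else None
    for b in range(n_perm):
        R = next(rot_iter) if rot_iter is not None else _random_rotation(rng)
        row = np.arange(n)
        for side, idx in cort.items():
            if idx.size == 0:
                continue
            R_side = R if side == "left" else mirror @ R @ mirror
            C = coords[idx]
            local = _greedy_assign(C @ R_side.T, C, rng)
            row[idx] = idx[local]
        if subcort.size:
            row[subcort] = subcort[rng.permutation(subcort.size)]
        perms[b] = row
    groups = tuple(
        tuple(idx.tolist()) for idx in (cort["left"], cort["right"], subcort) if idx.size
    )
    return SpinNull(
        permutations=perms,
        region_ids=tuple(atlas.region_ids.tolist()),
        seed=seed,
        closed_groups=groups,
    )


def _corr_rows(Xp: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of Xp with y (rows share x's spread)."""
    Xc = Xp - Xp.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    return (Xc @ yc) / denom


def spin_pvalue(x, y, spins: SpinNull, stat: str = "spearman") -> tuple[float, float]:
    """Spin-test p-value for the correlation of two parcellated maps.

    The null distribution permutes the first map by every spin row while
    holding the second fixed; p is two-sided on the absolute statistic,
    with +1 smoothing so p >= 1/(n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(spins.region_ids)
    if x.shape != (n,) or y.shape != (n,):
        raise ValueError("maps must align with the spin scope")
    if stat == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif stat != "pearson":
        raise ValueError("stat must be 'spearman' or 'pearson'")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant map: correlation undefined")
    observed = float(_corr_rows(x[None, :], y)[0])
    null = _corr_rows(x[spins.permutations], y)
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (spins.n_perm + 1.0)
    return observed, float(p)
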