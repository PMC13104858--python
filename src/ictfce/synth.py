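"""Synthetic inputs: smoothed statistic matrices, group data, voxel blobs.

``synth_stat_matrix`` emulates an edgewise t-statistic matrix with the
spatial correlation structure expected in FC data: a standard-normal
``N x N`` field is smoothed with a zero-padded 2D Gaussian filter whose
width scales proportionally with N (so the correlation structure occupies a
constant fraction of the matrix across parcellation sizes) and then
symmetrized by averaging with its transpose.

``synth_group_dataset`` plants a block effect into per-subject noise
matrices for power and calibration studies; ``synth_voxel_image`` builds
3D Gaussian-blob volumes.  All generators are bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import StatMatrix, ValidationError
from .inference import GroupDataset
from .voxel import VoxelImage

__all__ = [
    "SynthMatrixConfig",
    "SynthGroupConfig",
    "synth_stat_matrix",
    "synth_group_dataset",
    "synth_voxel_image",
    "DEFAULT_SIGMA_RATIO",
]

#: default filter width as a fraction of N; sigma = ratio * n_rois gives the
#: N=200 case a correlation length of ~2 entries, visible but far from
#: wiping out the map
DEFAULT_SIGMA_RATIO = 0.01

#: generator version tag recorded in provenance sidecars
GENERATOR_VERSION = "1"


@dataclass(frozen=True)
class SynthMatrixConfig:
    """Configuration for the smoothed-matrix generator.

    ``filter_sigma=None`` means ``DEFAULT_SIGMA_RATIO * n_rois``.  With
    ``standardize=True`` (default) the filtered field is rescaled to unit
    marginal standard deviation before symmetrizing, keeping the output on a
    t-statistic scale (raw smoothed white noise has SD ~ 1/(2*sigma*sqrt(pi)),
    which would push every statistic below common dh values).
    """

    n_rois: int = 200
    filter_sigma: float | None = None
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValidationError(f"n_rois must be >= 2, got {self.n_rois}")
        if self.filter_sigma is not None and self.filter_sigma < 0:
            raise ValidationError(f"filter_sigma must be >= 0, got {self.filter_sigma}")

    @property
    def sigma(self) -> float:
        if self.filter_sigma is None:
            return DEFAULT_SIGMA_RATIO * self.n_rois
        return self.filter_sigma


def synth_stat_matrix(c: SynthMatrixConfig) -> StatMatrix:
    """Standard-normal draw -> zero-padded 2D Gaussian filter -> symmetrize."""
    rng = np.random.default_rng(c.seed)
    a = rng.standard_normal((c.n_rois, c.n_rois))
    if c.sigma > 0:
        a = gaussian_filter(a, sigma=c.sigma, mode="constant", cval=0.0)
        if c.standardize:
            a = a / a.std()
    a = (a + a.T) / 2.0
    return StatMatrix(values=a)


@dataclass(frozen=True)
class SynthGroupConfig:
    """Two-group FC dataset with a planted block effect.

    Per-subject matrices are symmetric Gaussian noise (independent upper-
    triangle entries, SD ``noise_sd``); subjects of group B additionally get
    ``effect_size * noise_sd`` added at the effect edges.  The effect edges
    are either every within-block edge of ``effect_block`` (a tuple of node
    indices) or an explicit ``effect_edges`` list of (u, v) pairs.
    """

    n_per_group: int = 20
    n_rois: int = 30
    effect_block: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_edges: tuple[tuple[int, int], ...] | None = None
    effect_size: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError(
                f"need at least 2 subjects per group, got {self.n_per_group}"
            )
        if self.n_rois < 2:
            raise ValidationError(f"n_rois must be >= 2, got {self.n_rois}")
        if not self.noise_sd > 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        for u, v in self.resolved_effect_edges():
            if u == v:
                raise ValidationError(f"effect edge ({u}, {v}) lies on the diagonal")
            if not (0 <= u < self.n_rois and 0 <= v < self.n_rois):
                raise ValidationError(f"effect edge ({u}, {v}) out of range")

    def resolved_effect_edges(self) -> list[tuple[int, int]]:
        if self.effect_edges is not None:
            return [(min(u, v), max(u, v)) for u, v in self.effect_edges]
        block = sorted(self.effect_block)
        return [(u, v) for i, u in enumerate(block) for v in block[i + 1 :]]


def synth_group_dataset(c: SynthGroupConfig) -> GroupDataset:
    """Generate the two-group dataset described by ``c`` (group B = second half)."""
    rng = np.random.default_rng(c.seed)
    n_sub = 2 * c.n_per_group
    n = c.n_rois
    iu, iv = np.triu_indices(n, k=1)
    x = rng.normal(0.0, c.noise_sd, size=(n_sub, iu.size))
    effect = c.resolved_effect_edges()
    if effect and c.effect_size != 0:
        edge_pos = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(iu, iv))}
        cols = [edge_pos[e] for e in effect]
        x[c.n_per_group :, cols] += c.effect_size * c.noise_sd
    subjects = np.zeros((n_sub, n, n))
    subjects[:, iu, iv] = x
    subjects[:, iv, iu] = x
    groups = np.repeat([0, 1], c.n_per_group)
    return GroupDataset(subjects=subjects, groups=groups)


def synth_voxel_image(
    shape: tuple[int, int, int] = (12, 12, 12),
    n_blobs: int = 1,
    blob_sigma: float = 1.5,
    peak: float = 5.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    connectivity: int = 26,
) -> VoxelImage:
    """Gaussian blobs of amplitude ``peak`` on a zero background, full mask."""
    rng = np.random.default_rng(seed)
    stats = np.zeros(shape)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    for _ in range(n_blobs):
        center = [rng.uniform(1, s - 2) for s in shape]
        d2 = sum((g - ctr) ** 2 for g, ctr in zip(grids, center))
        stats += peak * np.exp(-d2 / (2.0 * blob_sigma**2))
    if noise_sd > 0:
        stats += rng.normal(0.0, noise_sd, size=shape)
    return VoxelImage(stats=stats, mask=None, connectivity=connectivity)
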