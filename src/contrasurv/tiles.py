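"""Image tiling, background filtering, and tile embedding I/O.

RGB images are cut into non-overlapping 224x224 patches from the top-left
corner (partial edge tiles discarded). A pixel counts as background when
all three channels are near-white (min(R,G,B) >= 220), which is the usual
intensity rule for H&E slides; a tile is dropped when its background
fraction reaches the threshold.

The stub encoder is a deterministic stand-in for a pretrained pathology
foundation model: tiles are downsampled to 16x16, flattened, passed
through a seeded Gaussian random projection and squashed elementwise to
(-1, 1). It is a pure function of (pixels, seed, dim), so identical tiles
always share an embedding. Externally computed embeddings can be dropped
in through the HDF5 loader instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .data import ValidationError
from .objectives import ConfigurationError

__all__ = ["TileSet", "TileEmbeddingSet", "tile_and_filter",
           "stub_encode_tiles", "save_tile_embeddings", "load_tile_embeddings"]

BACKGROUND_PIXEL_MIN = 220  # min(R,G,B) at or above this is background
STUB_DOWNSAMPLE = 16


@dataclass
class TileSet:
    patient_id: str
    tiles: list[tuple[int, int, np.ndarray]]  # (row_idx, col_idx, 224x224x3)
    source_magnification: str = "20x"
    n_discarded: int = 0

    def __post_init__(self) -> None:
        coords = [(r, c) for r, c, _ in self.tiles]
        if len(set(coords)) != len(coords):
            raise ValidationError("duplicate tile grid coordinates")
        for _, _, px in self.tiles:
            if px.shape[:2] != self.tiles[0][2].shape[:2] or px.ndim != 3:
                raise ValidationError("tiles must share an HxWx3 shape")

    def __len__(self) -> int:
        return len(self.tiles)


@dataclass
class TileEmbeddingSet:
    patient_id: str
    embeddings: np.ndarray  # tiles x dim
    tile_coords: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, float)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValidationError("embeddings must be a nonempty tiles x dim matrix")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValidationError("non-finite embedding values")


def tile_and_filter(image: np.ndarray, tile_size: int = 224,
                    background_threshold: float = 0.5,
                    patient_id: str = "unknown",
                    source_magnification: str = "20x") -> TileSet:
    """Grid-tile an RGB image and drop background-dominant tiles."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("expected an HxWx3 RGB array")
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        warnings.warn("image smaller than one tile; empty TileSet")
        return TileSet(patient_id, [], source_magnification)
    kept: list[tuple[int, int, np.ndarray]] = []
    discarded = 0
    for r in range(h // tile_size):
        for c in range(w // tile_size):
            tile = image[r * tile_size:(r + 1) * tile_size,
                         c * tile_size:(c + 1) * tile_size]
            bg = (tile.min(axis=2) >= BACKGROUND_PIXEL_MIN).mean()
            if bg >= background_threshold:
                discarded += 1
            else:
                kept.append((r, c, tile))
    return TileSet(patient_id, kept, source_magnification, n_discarded=discarded)


def _downsample(tile: np.ndarray, size: int) -> np.ndarray:
    """Block-mean downsample a square tile to size x size per channel."""
    h, w = tile.shape[:2]
    rows = np.array_split(np.arange(h), size)
    cols = np.array_split(np.arange(w), size)
    out = np.empty((size, size, tile.shape[2]))
    for i, ri in enumerate(rows):
        for j, cj in enumerate(cols):
            out[i, j] = tile[np.ix_(ri, cj)].mean(axis=(0, 1))
    return out


def stub_encode_tiles(tileset: TileSet, dim: int = 64,
                      seed: int = 0) -> TileEmbeddingSet:
    """Deterministic random-projection tile encoder.

    Embedding = tanh(W @ flatten(downsample(tile)/255 - 0.5)) with W drawn
    once from a seeded Gaussian, scaled by fan-in.
    """
    if dim < 1:
        raise ConfigurationError("dim must be >= 1")
    if len(tileset) == 0:
        raise ValidationError("cannot encode an empty TileSet")
    rng = np.random.default_rng(seed)
    in_dim = STUB_DOWNSAMPLE * STUB_DOWNSAMPLE * 3
    W = rng.standard_normal((dim, in_dim)) / np.sqrt(in_dim)
    rows = []
    for _, _, tile in tileset.tiles:
        x = _downsample(tile.astype(float), STUB_DOWNSAMPLE) / 255.0 - 0.5
        rows.append(np.tanh(W @ x.ravel()))
    return TileEmbeddingSet(tileset.patient_id, np.vstack(rows),
                            tile_coords=[(r, c) for r, c, _ in tileset.tiles])


def save_tile_embeddings(sets: dict[str, np.ndarray] | list[TileEmbeddingSet],
                         path: str | Path) -> None:
    """Write per-patient embedding matrices to one HDF5 container."""
    if isinstance(sets, list):
        sets = {s.patient_id: s.embeddings for s in sets}
    dims = {v.shape[1] for v in sets.values()}
    if len(dims) > 1:
        raise ValidationError(f"mixed embedding dimensions: {sorted(dims)}")
    with h5py.File(path, "w") as f:
        f.attrs["dim"] = dims.pop() if dims else 0
        for pid, emb in sets.items():
            f.create_dataset(str(pid), data=np.asarray(emb, np.float32))


def load_tile_embeddings(path: str | Path,
                         manifest_ids: list[str] | None = None,
                         ) -> dict[str, np.ndarray]:
    """Load per-patient embeddings; enforce dimension and manifest coverage."""
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        for pid in f.keys():
            arr = np.asarray(f[pid], dtype=float)
            if arr.ndim != 2:
                raise ValidationError(f"dataset {pid!r} is not 2-D")
            out[pid] = arr
    dims = {v.shape[1] for v in out.values()}
    if len(dims) > 1:
        raise ValidationError(f"mixed embedding dimensions: {sorted(dims)}")
    if manifest_ids is not None:
        missing = [p for p in manifest_ids if p not in out]
        if missing:
            raise ValidationError(f"embeddings missing for patients: {missing}")
    return out
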