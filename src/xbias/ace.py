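"""Automated concept extraction: superpixels -> embeddings -> clusters.

Concept candidates are proposed by multi-resolution SLIC-zero
segmentation of image tiles (three segment counts, giving concepts of
different granularity).  Each segment is rendered on a grey canvas
(value 127 everywhere off the segment) at its *original* location and
scale — patch size is not normalised because cell size is a meaningful
feature in histology.  Canvases are embedded at the network's 16-d
fully connected layer; convolutional feature maps are deliberately not
used because they are not spatially invariant and make the clustering
group patches by location rather than appearance.  Embeddings are
clustered with k-means, and clusters survive only if they are large
enough and draw from enough distinct tiles; a concept keeps at most
``n_patches`` members, the ones closest (l2) to the cluster center.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import slic
from sklearn.cluster import KMeans

from . import cnn
from .synthgen import Tile

GREY = 127
LEVEL_NAMES = ("coarse", "mid", "fine")


@dataclass
class ConceptPatch:
    canvas: np.ndarray            # (T,T,3) uint8, off-mask = 127
    mask: np.ndarray              # (T,T) bool
    source_tile: int              # tile_id
    level: str                    # coarse | mid | fine
    index: int = -1               # position in the patch pool


@dataclass
class Concept:
    id: int
    patches: list[ConceptPatch]   # ordered by distance to center
    center: np.ndarray
    n_members_total: int
    target_layer: str = "fc16"

    @property
    def patch_indices(self) -> list[int]:
        return [p.index for p in self.patches]


@dataclass
class ACEConfig:
    # Per-level SLIC segment counts.  The counts are tile-size independent:
    # the generator scales all tile content (nucleus radii, marker side)
    # linearly with the tile side, so a fixed count preserves the relative
    # geometry of segments and image features at every tile size.
    segments: tuple[int, int, int] = (15, 50, 80)
    min_pixels_frac: float = 0.005
    n_patches: int = 40
    min_members: int = 20
    min_tiles: int = 5
    k: int = 5
    layer: str = "fc16"


def segment_tile(pixels: np.ndarray, n_segments: int) -> list[np.ndarray]:
    """SLIC-zero superpixels as a list of disjoint boolean masks that
    cover the tile."""
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if pixels.std() == 0:
        warnings.warn("degenerate constant image: single segment")
        return [np.ones(pixels.shape[:2], dtype=bool)]
    labels = slic(pixels, n_segments=n_segments, slic_zero=True,
                  start_label=0, enforce_connectivity=True,
                  channel_axis=-1)
    return [labels == lab for lab in np.unique(labels)]


def make_patch(pixels: np.ndarray, mask: np.ndarray, source_tile: int = -1,
               level: str = "mid", min_pixels: int = 1) -> ConceptPatch | None:
    """Segment pixels at their original location on a grey-127 canvas;
    returns None for segments below the size floor."""
    if not mask.any():
        raise ValueError("empty mask")
    if int(mask.sum()) < min_pixels:
        return None
    canvas = np.full_like(pixels, GREY)
    canvas[mask] = pixels[mask]
    return ConceptPatch(canvas, mask.copy(), source_tile, level)


def propose_patches(tiles: list[Tile], cfg: ACEConfig | None = None
                    ) -> list[ConceptPatch]:
    """Pool segments of all tiles across the three SLIC resolutions."""
    cfg = cfg or ACEConfig()
    patches: list[ConceptPatch] = []
    for tile in tiles:
        t = tile.pixels.shape[0]
        min_pixels = max(1, int(cfg.min_pixels_frac * t * t))
        for level_name, n_seg in zip(LEVEL_NAMES, cfg.segments):
            for mask in segment_tile(tile.pixels, n_seg):
                p = make_patch(tile.pixels, mask, tile.tile_id, level_name,
                               min_pixels)
                if p is not None:
                    patches.append(p)
    for i, p in enumerate(patches):
        p.index = i
    return patches


def embed_patches(patches: list[ConceptPatch], model: cnn.TileCNN,
                  layer: str = "fc16") -> np.ndarray:
    """One activation row per patch; canvases are scaled to [0,1] first."""
    if not patches:
        return np.zeros((0, 16), dtype=np.float32)
    x = np.stack([p.canvas for p in patches]).astype(np.float32) / 255.0
    return cnn.activations(model, layer, x)


def cluster_concepts(embeddings: np.ndarray, k: int, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """k-means (k-means++ init) labels and centers."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(embeddings) < k:
        raise ValueError("fewer embeddings than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(embeddings)
    return labels, km.cluster_centers_


def select_concepts(patches: list[ConceptPatch], embeddings: np.ndarray,
                    labels: np.ndarray, centers: np.ndarray,
                    cfg: ACEConfig | None = None) -> list[Concept]:
    """Apply the cluster filters and keep the ``n_patches`` members
    closest to each surviving center (ties broken by patch index)."""
    cfg = cfg or ACEConfig()
    concepts: list[Concept] = []
    for cid in range(len(centers)):
        member_idx = np.nonzero(labels == cid)[0]
        if len(member_idx) < cfg.min_members:
            continue
        tiles_used = {patches[i].source_tile for i in member_idx}
        if len(tiles_used) < cfg.min_tiles:
            continue
        d = np.linalg.norm(embeddings[member_idx] - centers[cid], axis=1)
        order = np.lexsort((member_idx, d))[:cfg.n_patches]
        chosen = [patches[member_idx[i]] for i in order]
        concepts.append(Concept(cid, chosen, centers[cid].copy(),
                                len(member_idx), cfg.layer))
    if not concepts:
        warnings.warn("all clusters were filtered out")
    return concepts


@dataclass
class ConceptExtraction:
    """Everything downstream consumers need: the selected concepts, the
    full patch pool (for random counterexamples) and its embeddings."""
    concepts: list[Concept]
    pool: list[ConceptPatch] = field(repr=False)
    embeddings: np.ndarray = field(repr=False)
    layer: str = "fc16"


def extract_concepts(model: cnn.TileCNN, tiles: list[Tile],
                     cfg: ACEConfig | None = None, seed: int = 0
                     ) -> ConceptExtraction:
    """Full ACE steps 1–2 on a set of tiles."""
    cfg = cfg or ACEConfig()
    pool = propose_patches(tiles, cfg)
    emb = embed_patches(pool, model, cfg.layer)
    labels, centers = cluster_concepts(emb, cfg.k, seed)
    concepts = select_concepts(pool, emb, labels, centers, cfg)
    return ConceptExtraction(concepts, pool, emb, cfg.layer)


def concept_gallery(concept: Concept, path: str, max_patches: int = 20,
                    crop: bool = True) -> None:
    """Contact sheet of a concept's patches (cropped to the mask bounding
    box for viewing; network inputs are never cropped)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    patches = concept.patches[:max_patches]
    cols = min(5, len(patches))
    rows = math.ceil(len(patches) / cols)
    fig, axes = plt.subplots(rows, cols, figsize=(2 * cols, 2 * rows),
                             squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, p in zip(axes.ravel(), patches):
        img = p.canvas
        if crop:
            rr, cc = np.nonzero(p.mask)
            img = img[rr.min():rr.max() + 1, cc.min():cc.max() + 1]
        ax.imshow(img)
    fig.suptitle(f"concept {concept.id} "
                 f"({concept.n_members_total} members)")
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)
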