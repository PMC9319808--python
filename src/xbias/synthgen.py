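"""Synthetic two-class histology-like tiles with controllable biases.

The generator emulates the statistical structure of H&E-stained skin
tiles without any real data: a pink stroma texture, dark elliptical cell
nuclei whose density and size separate the two classes (the positive,
"cancerous" class has more and larger nuclei), an optional wavy collagen
stratum standing in for reticular dermis, and two source appearance
regimes (scanner/stain settings) where source B is globally brighter
with compressed colour variation.  Tiles are grouped into virtual slides
that carry a deterministic per-slide stain/density jitter, and dataset
splits are slide-disjoint.

Four bias designs can be planted on top of an otherwise unbiased
dataset:

``class_ratio``
    positive tiles are admitted to the training pool with probability
    ``1 - ratio_reduction`` (default 0.5, giving roughly 2:1
    negative:positive), validation/test untouched;
``measurement``
    class label is perfectly confounded with the source regime in every
    split and no appearance normalisation is applied;
``sampling``
    training tiles of the negative class exclude a texture stratum
    (default collagen) that validation/test retain;
``class_correlated``
    a small red square is drawn in the upper-left corner of every
    positive tile in every split.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

VALID_STRATA = frozenset({"nuclei_dense", "nuclei_sparse", "collagen", "background"})
BIAS_KINDS = ("none", "class_ratio", "measurement", "sampling", "class_correlated")

POSITIVE, NEGATIVE = "positive", "negative"


class ConfigurationError(ValueError):
    pass


class WhiteFractionError(RuntimeError):
    """Raised when a tile cannot satisfy the near-white area limit."""


@dataclass(frozen=True)
class MarkerSpec:
    size: int
    offset: tuple[int, int]
    color: tuple[int, int, int] = (255, 0, 0)

    @classmethod
    def default(cls, tile_size: int) -> "MarkerSpec":
        off = max(1, round(tile_size / 24))
        return cls(size=max(2, round(tile_size / 12)), offset=(off, off))


@dataclass(frozen=True)
class SourceShift:
    """Uniform per-channel affine map y = gain*x + offset.

    The default emulates a second scanner/stain regime: +12% brightness
    and a 30% contraction of each channel toward a reference stroma
    colour (smaller colour variation).
    """

    gain: tuple[float, float, float]
    offset: tuple[float, float, float]

    @classmethod
    def default(cls, brightness: float = 1.12, contraction: float = 0.7,
                reference: tuple[float, float, float] = (232.0, 190.0, 205.0)
                ) -> "SourceShift":
        gain = tuple(brightness * contraction for _ in range(3))
        offset = tuple(brightness * (1.0 - contraction) * r for r in reference)
        return cls(gain, offset)  # type: ignore[arg-type]

    @classmethod
    def identity(cls) -> "SourceShift":
        return cls((1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@dataclass(frozen=True)
class GenParams:
    """Rendering parameters; densities/radii are stated at 96 px scale
    and rescaled with tile area."""

    tile_size: int = 96
    nucleus_rate_dense: float = 20.0
    nucleus_rate_sparse: float = 14.0
    nucleus_radius_dense: float = 4.2
    nucleus_radius_sparse: float = 3.6
    nucleus_color: tuple[int, int, int] = (95, 70, 140)
    stroma_color: tuple[int, int, int] = (232, 190, 205)
    collagen_color: tuple[int, int, int] = (205, 150, 170)
    slide_color_jitter: float = 8.0
    slide_density_sigma: float = 0.35
    collagen_prob_positive: float = 0.15
    collagen_prob_negative: float = 0.5
    white_threshold: int = 240
    max_white_fraction: float = 0.10
    appearance_seed: int = 0
    source_shift: SourceShift = field(default_factory=SourceShift.default)


@dataclass(frozen=True)
class BiasConfig:
    kind: str = "none"
    ratio_reduction: float = 0.5
    excluded_stratum: str = "collagen"
    marker: MarkerSpec | None = None
    source_shift: SourceShift | None = None
    positive_source: str = "A"

    def __post_init__(self) -> None:
        if self.kind not in BIAS_KINDS:
            raise ConfigurationError(f"unknown bias kind {self.kind!r}")
        if not 0.0 <= self.ratio_reduction < 1.0:
            raise ConfigurationError("ratio_reduction must be in [0, 1)")
        if self.excluded_stratum not in VALID_STRATA:
            raise ConfigurationError(
                f"unknown stratum {self.excluded_stratum!r}")


@dataclass
class Tile:
    pixels: np.ndarray          # (T, T, 3) uint8
    label: str                  # "positive" | "negative"
    source: str                 # "A" | "B"
    slide_id: int
    strata: frozenset[str]
    has_marker: bool = False
    nucleus_mask: np.ndarray | None = None
    collagen_mask: np.ndarray | None = None
    tile_id: int = -1

    @property
    def y(self) -> int:
        return 1 if self.label == POSITIVE else 0


@dataclass
class DatasetSplit:
    train: list[Tile]
    val: list[Tile]
    test: list[Tile]
    manifest: pd.DataFrame

    def tiles(self, split: str) -> list[Tile]:
        return getattr(self, split)


# ---------------------------------------------------------------------
# tile rendering
# ---------------------------------------------------------------------

def _slide_appearance(slide_id: int, params: GenParams
                      ) -> tuple[np.ndarray, float]:
    """Deterministic per-slide stain jitter and nucleus-density factor."""
    rng = np.random.default_rng(
        np.random.SeedSequence([params.appearance_seed, 7919, slide_id]))
    color_shift = rng.uniform(-params.slide_color_jitter,
                              params.slide_color_jitter, size=3)
    density = float(np.exp(rng.normal(0.0, params.slide_density_sigma)))
    return color_shift, density


def _render(label: str, slide_id: int, strata: frozenset[str],
            rng: np.random.Generator, params: GenParams
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = params.tile_size
    f = t / 96.0
    color_shift, density_factor = _slide_appearance(slide_id, params)

    tissue = strata & {"nuclei_dense", "nuclei_sparse", "collagen"}
    if tissue:
        base = np.asarray(params.stroma_color, dtype=np.float64) + color_shift
        canvas = np.broadcast_to(base, (t, t, 3)).copy()
        lowfreq = gaussian_filter(rng.normal(0.0, 1.0, (t, t)), sigma=6.0 * f)
        canvas *= (1.0 + 0.06 * lowfreq)[..., None]
        canvas += rng.normal(0.0, 3.0, (t, t, 3))
    else:
        canvas = np.full((t, t, 3), 248.0) + rng.normal(0.0, 2.0, (t, t, 3))

    collagen_mask = np.zeros((t, t), dtype=bool)
    if "collagen" in strata:
        yy, xx = np.mgrid[0:t, 0:t]
        wavelength = rng.uniform(18.0, 30.0) * f
        amp = rng.uniform(3.0, 7.0) * f
        phase = rng.uniform(0.0, 2 * np.pi)
        spacing = rng.uniform(9.0, 14.0) * f
        band = (yy + amp * np.sin(2 * np.pi * xx / wavelength + phase)) % spacing
        collagen_mask = band < (0.45 * spacing)
        col = np.asarray(params.collagen_color, dtype=np.float64) + color_shift
        canvas[collagen_mask] = 0.35 * canvas[collagen_mask] + 0.65 * col

    nucleus_mask = np.zeros((t, t), dtype=bool)
    if tissue & {"nuclei_dense", "nuclei_sparse"}:
        dense = "nuclei_dense" in strata
        rate = (params.nucleus_rate_dense if dense
                else params.nucleus_rate_sparse) * f * f * density_factor
        radius = (params.nucleus_radius_dense if dense
                  else params.nucleus_radius_sparse) * f
        count = rng.poisson(rate)
        for _ in range(count):
            cy, cx = rng.uniform(0, t, size=2)
            a = max(1.0, radius * rng.uniform(0.75, 1.25))
            b = max(1.0, radius * rng.uniform(0.75, 1.25))
            rot = rng.uniform(0.0, np.pi)
            rr, cc = ellipse(cy, cx, a, b, shape=(t, t), rotation=rot)
            nucleus_mask[rr, cc] = True
            ncol = (np.asarray(params.nucleus_color, dtype=np.float64)
                    + rng.normal(0.0, 6.0, 3))
            canvas[rr, cc] = 0.15 * canvas[rr, cc] + 0.85 * ncol

    if "background" in strata and tissue:
        # a limited near-white pocket (torn tissue / glass)
        side = int(t * 0.28)
        r0 = rng.integers(0, t - side + 1)
        c0 = rng.integers(0, t - side + 1)
        canvas[r0:r0 + side, c0:c0 + side] = 249.0 + rng.normal(
            0.0, 1.5, (side, side, 3))

    return np.clip(canvas, 0, 255).astype(np.uint8), nucleus_mask, collagen_mask


def white_fraction(pixels: np.ndarray, threshold: int = 240) -> float:
    """Fraction of pixels whose three channels are all >= threshold."""
    return float(np.mean(np.all(pixels >= threshold, axis=-1)))


def apply_source_shift(pixels: np.ndarray, shift: SourceShift) -> np.ndarray:
    """Apply the uniform per-channel affine appearance map, clipped to
    the uint8 range."""
    out = pixels.astype(np.float64)
    out = out * np.asarray(shift.gain) + np.asarray(shift.offset)
    return np.clip(out, 0, 255).astype(np.uint8)


def generate_tile(label: str, source: str, slide_id: int,
                  strata, seed: int,
                  params: GenParams | None = None,
                  max_attempts: int = 8) -> Tile:
    """Render one tile deterministically from its arguments.

    Tiles are regenerated with perturbed sub-seeds until the near-white
    area constraint (<= 10% of pixels) holds; tiles that cannot satisfy
    it (e.g. pure background) raise :class:`WhiteFractionError`.
    """
    params = params or GenParams()
    strata = frozenset(strata)
    if not strata:
        raise ConfigurationError("strata must be non-empty")
    unknown = strata - VALID_STRATA
    if unknown:
        raise ConfigurationError(f"unknown strata {sorted(unknown)}")
    if label not in (POSITIVE, NEGATIVE):
        raise ConfigurationError(f"unknown label {label!r}")
    if source not in ("A", "B"):
        raise ConfigurationError(f"unknown source {source!r}")

    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, attempt, slide_id]))
        pixels, nmask, cmask = _render(label, slide_id, strata, rng, params)
        if source == "B":
            pixels = apply_source_shift(pixels, params.source_shift)
        if white_fraction(pixels, params.white_threshold) <= params.max_white_fraction:
            return Tile(pixels, label, source, slide_id, strata,
                        nucleus_mask=nmask, collagen_mask=cmask)
    raise WhiteFractionError(
        f"tile (label={label}, strata={sorted(strata)}) exceeds the "
        f"{params.max_white_fraction:.0%} near-white limit")


def inject_marker(tile: Tile, marker: MarkerSpec) -> Tile:
    """Draw the class-correlated marker (a flat-colour square) on a
    positive tile; all pixels outside the marker are untouched."""
    if tile.label != POSITIVE:
        raise ConfigurationError("marker is planted on positive tiles only")
    t = tile.pixels.shape[0]
    r0, c0 = marker.offset
    if marker.size < 0 or r0 < 0 or c0 < 0 or \
            r0 + marker.size > t or c0 + marker.size > t:
        raise ConfigurationError("marker outside image bounds")
    if marker.size == 0:
        return tile
    pixels = tile.pixels.copy()
    pixels[r0:r0 + marker.size, c0:c0 + marker.size] = marker.color
    return replace(tile, pixels=pixels, has_marker=True)


def marker_mask(tile_size: int, marker: MarkerSpec) -> np.ndarray:
    m = np.zeros((tile_size, tile_size), dtype=bool)
    r0, c0 = marker.offset
    m[r0:r0 + marker.size, c0:c0 + marker.size] = True
    return m


# ---------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------

def _split_slides(n_slides: int, rng: np.random.Generator
                  ) -> dict[str, list[int]]:
    """Slide-disjoint 66.67/16.67/16.67 split."""
    order = list(rng.permutation(n_slides))
    n_val = max(1, round(n_slides / 6))
    n_test = max(1, round(n_slides / 6))
    return {"test": order[:n_test],
            "val": order[n_test:n_test + n_val],
            "train": order[n_test + n_val:]}


def _tile_seed(seed: int, slide_id: int, index: int) -> int:
    ss = np.random.SeedSequence([seed, 104729, slide_id, index])
    return int(ss.generate_state(1)[0])


def plan_dataset(bias: BiasConfig, n_slides: int = 30,
                 tiles_per_slide: int = 40, seed: int = 0,
                 params: GenParams | None = None) -> pd.DataFrame:
    """Deterministic tile-level assignments, before any rendering.

    Returns one row per admitted tile with columns split, slide_id,
    label, source, strata (semicolon-joined), marker (bool) and the
    per-tile render seed.  With ``kind='none'`` the label is independent
    of both source and marker.  Labels are drawn per tile (a slide
    contains both tissue types) except under measurement bias, where
    slides are class-pure so the slide-level source regime can be
    perfectly confounded with the label in every split.
    """
    params = params or GenParams()
    if n_slides < 6:
        raise ConfigurationError("need at least 6 slides for three splits")
    if bias.kind == "sampling" and bias.excluded_stratum in (
            "nuclei_dense", "nuclei_sparse"):
        raise ConfigurationError(
            "excluding the nucleus stratum leaves no class signal")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    split_map = _split_slides(n_slides, rng)

    slide_source: dict[int, str] = {}
    slide_label: dict[int, str | None] = {}
    for split, slides in split_map.items():
        for i, s in enumerate(slides):
            if bias.kind == "measurement":
                # alternate class-pure slides so each split keeps both
                # classes; source follows the label exactly (confound)
                lab = POSITIVE if i % 2 == 0 else NEGATIVE
                slide_label[s] = lab
                pos_src = bias.positive_source
                neg_src = "B" if pos_src == "A" else "A"
                slide_source[s] = pos_src if lab == POSITIVE else neg_src
            else:
                slide_label[s] = None
                slide_source[s] = "A" if i % 2 == 0 else "B"

    rows = []
    for split in ("train", "val", "test"):
        for s in split_map[split]:
            for t_idx in range(tiles_per_slide):
                tseed = _tile_seed(seed, s, t_idx)
                trng = np.random.default_rng(tseed)
                lab = slide_label[s]
                if lab is None:
                    lab = POSITIVE if trng.random() < 0.5 else NEGATIVE

                if bias.kind == "class_ratio" and split == "train" \
                        and lab == POSITIVE:
                    if trng.random() < bias.ratio_reduction:
                        continue  # rejection-sampled out of the train pool

                p_col = (params.collagen_prob_positive if lab == POSITIVE
                         else params.collagen_prob_negative)
                strata = {"nuclei_dense" if lab == POSITIVE else "nuclei_sparse"}
                if trng.random() < p_col:
                    strata.add("collagen")
                if bias.kind == "sampling" and split == "train" \
                        and lab == NEGATIVE:
                    strata.discard(bias.excluded_stratum)

                rows.append({
                    "split": split, "slide_id": s, "label": lab,
                    "source": slide_source[s],
                    "strata": ";".join(sorted(strata)),
                    "marker": bias.kind == "class_correlated" and lab == POSITIVE,
                    "render_seed": tseed,
                })
    return pd.DataFrame(rows)


def build_dataset(bias: BiasConfig, n_slides: int = 30,
                  tiles_per_slide: int = 40, seed: int = 0,
                  params: GenParams | None = None) -> DatasetSplit:
    """Render the :func:`plan_dataset` assignments into a slide-grouped
    tile dataset with the requested bias planted."""
    params = params or GenParams()
    marker = bias.marker or MarkerSpec.default(params.tile_size)
    if bias.source_shift is not None:
        params = replace(params, source_shift=bias.source_shift)
    plan = plan_dataset(bias, n_slides, tiles_per_slide, seed, params)

    tiles: dict[str, list[Tile]] = {"train": [], "val": [], "test": []}
    for tile_id, row in enumerate(plan.itertuples(index=False)):
        tile = generate_tile(row.label, row.source, int(row.slide_id),
                             row.strata.split(";"), int(row.render_seed),
                             params=params)
        if row.marker:
            tile = inject_marker(tile, marker)
        tile.tile_id = tile_id
        tiles[row.split].append(tile)

    manifest = _manifest(tiles)
    return DatasetSplit(tiles["train"], tiles["val"], tiles["test"], manifest)


def _manifest(tiles: dict[str, list[Tile]]) -> pd.DataFrame:
    rows = []
    for split in ("train", "val", "test"):
        for tile in tiles[split]:
            rows.append({
                "path": f"{split}/tile_{tile.tile_id:05d}.png",
                "label": tile.label,
                "source": tile.source,
                "slide_id": tile.slide_id,
                "split": split,
                "has_marker": tile.has_marker,
                "strata": ";".join(sorted(tile.strata)),
            })
    return pd.DataFrame(rows)


def tiles_to_arrays(tiles: list[Tile]) -> tuple[np.ndarray, np.ndarray]:
    """Stack tiles into (N,T,T,3) uint8 pixels and 0/1 labels."""
    x = np.stack([t.pixels for t in tiles])
    y = np.array([t.y for t in tiles], dtype=np.int64)
    return x, y


def save_dataset(ds: DatasetSplit, outdir: str) -> str:
    """Write tiles as PNG plus the CSV manifest; returns the manifest path."""
    for split in ("train", "val", "test"):
        os.makedirs(os.path.join(outdir, split), exist_ok=True)
        for tile in ds.tiles(split):
            Image.fromarray(tile.pixels).save(
                os.path.join(outdir, split, f"tile_{tile.tile_id:05d}.png"))
    path = os.path.join(outdir, "manifest.csv")
    ds.manifest.to_csv(path, index=False)
    return path


def load_dataset(outdir: str) -> DatasetSplit:
    manifest = pd.read_csv(os.path.join(outdir, "manifest.csv"))
    tiles: dict[str, list[Tile]] = {"train": [], "val": [], "test": []}
    for _, row in manifest.iterrows():
        pixels = np.asarray(Image.open(os.path.join(outdir, row["path"])))
        tile = Tile(pixels, row["label"], row["source"], int(row["slide_id"]),
                    frozenset(str(row["strata"]).split(";")),
                    has_marker=bool(row["has_marker"]))
        tile.tile_id = int(os.path.splitext(
            os.path.basename(row["path"]))[0].split("_")[1])
        tiles[row["split"]].append(tile)
    return DatasetSplit(tiles["train"], tiles["val"], tiles["test"], manifest)
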