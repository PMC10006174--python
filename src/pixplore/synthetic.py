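"""Synthetic multiplexed tissue images with known pixel-class structure.

Real IMC datasets of the kind this pipeline targets (fetal intestinal ROIs
with lymphoid follicles) live in external repositories; every downstream
stage is instead tested on generated images whose ground truth is known by
construction. A :class:`SyntheticSpec` plants geometric regions (rectangles
and discs), assigns pixel classes with per-region mixing fractions, stamps
each class's per-marker mean intensity and applies count-like noise —
Poisson with the class mean as rate, or mean-preserving multiplicative
lognormal.

Rasterization uses pixel-center inclusion: pixel (r, c) belongs to a disc
iff its integer center lies inside (boundary inclusive), and to a rectangle
``(top, left, height, width)`` iff ``top <= r < top+height`` and likewise
for columns. All randomness flows from the explicit ``seed`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io import ChannelStack, MarkerPanel, Roi, RoiSet

VALID_GROUPS = {"LF", "non-LF", "background"}


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: rows [top, top+height), cols [left, left+width)."""

    top: int
    left: int
    height: int
    width: int

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.meshgrid(
            np.arange(shape[0]), np.arange(shape[1]), indexing="ij"
        )
        return (
            (rr >= self.top)
            & (rr < self.top + self.height)
            & (cc >= self.left)
            & (cc < self.left + self.width)
        )

    def within(self, shape: tuple[int, int]) -> bool:
        return (
            0 <= self.top
            and 0 <= self.left
            and self.top + self.height <= shape[0]
            and self.left + self.width <= shape[1]
        )


@dataclass(frozen=True)
class Disc:
    """Disc in pixel coordinates; pixel centers (r, c) with distance <= radius."""

    center_row: float
    center_col: float
    radius: float

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.meshgrid(
            np.arange(shape[0]), np.arange(shape[1]), indexing="ij"
        )
        return (rr - self.center_row) ** 2 + (
            cc - self.center_col
        ) ** 2 <= self.radius**2

    def within(self, shape: tuple[int, int]) -> bool:
        return (
            self.center_row - self.radius >= -0.5
            and self.center_col - self.radius >= -0.5
            and self.center_row + self.radius <= shape[0] - 0.5
            and self.center_col + self.radius <= shape[1] - 0.5
        )


@dataclass(frozen=True)
class Region:
    """A named planted region carrying a group tag for ROI bookkeeping.

    ``exclusive`` regions may not overlap another region with a different
    class mixture; non-exclusive regions are painted in list order (later
    regions overwrite earlier ones), which lets a follicle disc sit inside
    a lamina-propria rectangle.
    """

    name: str
    geometry: Rect | Disc
    group: str
    exclusive: bool = True

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"region {self.name!r}: group {self.group!r} not in {sorted(VALID_GROUPS)}"
            )


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic multiplexed image.

    Parameters
    ----------
    image_height, image_width
        Raster dimensions in pixels (1 px = 1 µm).
    regions
        Planted geometries with group tags (LF / non-LF / background).
    classes
        Mapping class name → {marker: mean intensity (counts, >= 0)}.
    class_map_rule
        Mapping region name → {class name: mixing fraction}; fractions per
        region are in [0, 1] and sum to 1 (±1e-9). Pixels inside the region
        draw their class i.i.d. from this mixture.
    noise_model
        "poisson", or "lognormal" with ``lognormal_sigma`` (sigma = 0 means
        noise-free).
    seed
        Integer seed; identical (spec, seed) gives bit-identical output.
    """

    image_height: int
    image_width: int
    regions: list[Region]
    classes: dict[str, dict[str, float]]
    class_map_rule: dict[str, dict[str, float]]
    noise_model: str = "poisson"
    lognormal_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height, self.image_width)

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)

    @property
    def markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for sig in self.classes.values():
            for m in sig:
                seen.setdefault(m)
        return list(seen)

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if self.noise_model not in {"poisson", "lognormal"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal sigma must be >= 0")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError(f"region names must be unique, got {names}")
        for r in self.regions:
            if not r.geometry.within(self.shape):
                raise ValueError(
                    f"region {r.name!r} does not lie within image bounds {self.shape}"
                )
        if not self.classes:
            raise ValueError("at least one class required")
        for cname, sig in self.classes.items():
            for m, mu in sig.items():
                if mu < 0:
                    raise ValueError(
                        f"class {cname!r}: mean intensity for {m} is negative"
                    )
        for rname, mix in self.class_map_rule.items():
            if rname not in names:
                raise ValueError(f"class_map_rule names unknown region {rname!r}")
            for cname, frac in mix.items():
                if cname not in self.classes:
                    raise ValueError(
                        f"region {rname!r} mixes unknown class {cname!r}"
                    )
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(
                        f"region {rname!r}: fraction for {cname!r} outside [0, 1]"
                    )
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"region {rname!r}: mixing fractions sum to "
                    f"{sum(mix.values())}, expected 1"
                )


@dataclass
class GroundTruth:
    """Known pixel classes for a generated image.

    ``label_map`` is H×W with 0 = background and k >= 1 the 1-based index
    of the k-th declared class; ``roi_set`` carries the non-background
    planted regions for quantification tests.
    """

    label_map: np.ndarray
    roi_set: RoiSet
    class_names: list[str] = field(default_factory=list)

    def class_mask(self, class_name: str) -> np.ndarray:
        return self.label_map == (self.class_names.index(class_name) + 1)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _apply_noise(
    means: np.ndarray, model: str, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    if model == "poisson":
        return rng.poisson(means).astype(np.float64)
    if sigma == 0.0:
        return means.copy()
    # mean-preserving multiplicative lognormal: E[exp(N(-s^2/2, s^2))] = 1
    factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=means.shape)
    return means * factor


def generate_multiplex_image(spec: SyntheticSpec) -> tuple[ChannelStack, GroundTruth]:
    """Render a SyntheticSpec into a multichannel image plus its ground truth.

    Pixels covered by no region (or by a region with no class mixture) are
    background: label 0, zero mean in every channel. Overlap between two
    exclusive regions with different class mixtures is an error naming the
    colliding regions.
    """
    spec.validate()
    shape = spec.shape
    masks = {r.name: r.geometry.rasterize(shape) for r in spec.regions}

    for i, a in enumerate(spec.regions):
        for b in spec.regions[i + 1 :]:
            if not (a.exclusive and b.exclusive):
                continue
            if spec.class_map_rule.get(a.name) == spec.class_map_rule.get(b.name):
                continue
            if np.any(masks[a.name] & masks[b.name]):
                raise ValueError(
                    f"regions {a.name!r} and {b.name!r} overlap but assign "
                    "conflicting exclusive classes"
                )

    rng = np.random.default_rng(spec.seed)
    class_names = spec.class_names
    class_index = {c: i + 1 for i, c in enumerate(class_names)}
    label_map = np.zeros(shape, dtype=np.int32)

    # painter's order: later regions overwrite earlier ones
    for region in spec.regions:
        mix = spec.class_map_rule.get(region.name)
        if not mix:
            continue
        mask = masks[region.name]
        n = int(mask.sum())
        mix_classes = list(mix)
        probs = np.array([mix[c] for c in mix_classes])
        draw = rng.choice(len(mix_classes), size=n, p=probs / probs.sum())
        labels = np.array([class_index[c] for c in mix_classes])[draw]
        label_map[mask] = labels

    markers = spec.markers
    mean_lut = np.zeros((len(class_names) + 1, len(markers)))
    for cname, sig in spec.classes.items():
        for j, m in enumerate(markers):
            mean_lut[class_index[cname], j] = sig.get(m, 0.0)

    means = mean_lut[label_map]  # H×W×M
    noisy = _apply_noise(means, spec.noise_model, spec.lognormal_sigma, rng)
    data = np.moveaxis(noisy, 2, 0)  # C×H×W

    panel = MarkerPanel.from_markers(markers)
    rois = [
        Roi(name=r.name, mask=masks[r.name], group=r.group)
        for r in spec.regions
        if r.group != "background"
    ]
    gt = GroundTruth(
        label_map=label_map, roi_set=RoiSet(rois), class_names=class_names
    )
    return ChannelStack(data, panel), gt


def generate_pixel_clusters(
    n_per_class: int | Sequence[int],
    signatures: Mapping[str, Mapping[str, float]],
    noise_model: str = "lognormal",
    sigma: float = 0.1,
    seed: int = 0,
):
    """Tabular fixture: rows drawn around per-class marker signatures.

    Returns a :class:`~pixplore.preprocess.PixelTable` (synthetic raster
    coordinates laid out row-major) and the row-aligned integer class
    labels. Used to exercise hierarchy and embedding stages without images.
    """
    from .preprocess import PixelTable

    if not signatures:
        raise ValueError("signature table must not be empty")
    names = list(signatures)
    if isinstance(n_per_class, (int, np.integer)):
        counts = [int(n_per_class)] * len(names)
    else:
        counts = [int(n) for n in n_per_class]
        if len(counts) != len(names):
            raise ValueError("n_per_class length must match number of classes")
    if any(n < 1 for n in counts):
        raise ValueError("n_per_class must be >= 1")

    markers: list[str] = []
    for sig in signatures.values():
        for m in sig:
            if m not in markers:
                markers.append(m)

    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k, (cname, n) in enumerate(zip(names, counts)):
        mu = np.array([signatures[cname].get(m, 0.0) for m in markers])
        means = np.tile(mu, (n, 1))
        blocks.append(_apply_noise(means, noise_model, sigma, rng))
        labels.append(np.full(n, k, dtype=np.int64))
    values = np.vstack(blocks)
    labels = np.concatenate(labels)

    total = values.shape[0]
    width = int(np.ceil(np.sqrt(total)))
    idx = np.arange(total)
    coords = np.column_stack([idx // width, idx % width])
    table = PixelTable(values=values, coords=coords, marker_names=markers)
    return table, labels


# ---------------------------------------------------------------------------
# Spec files and a ready-made demo fixture
# ---------------------------------------------------------------------------

def _geometry_from_dict(d: Mapping) -> Rect | Disc:
    kind = d.get("kind", "rect")
    if kind in {"rect", "rectangle"}:
        return Rect(int(d["top"]), int(d["left"]), int(d["height"]), int(d["width"]))
    if kind == "disc":
        return Disc(float(d["center_row"]), float(d["center_col"]), float(d["radius"]))
    raise ValueError(f"unknown geometry kind {kind!r}")


def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a SyntheticSpec from a YAML file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    regions = [
        Region(
            name=r["name"],
            geometry=_geometry_from_dict(r["geometry"]),
            group=r.get("group", "background"),
            exclusive=bool(r.get("exclusive", True)),
        )
        for r in raw.get("regions", [])
    ]
    noise = raw.get("noise_model", "poisson")
    sigma = 0.0
    if isinstance(noise, Mapping):
        sigma = float(noise.get("sigma", 0.0))
        noise = noise["kind"]
    else:
        sigma = float(raw.get("lognormal_sigma", 0.0))
    return SyntheticSpec(
        image_height=int(raw["image_height"]),
        image_width=int(raw["image_width"]),
        regions=regions,
        classes={c: dict(sig) for c, sig in raw["classes"].items()},
        class_map_rule={r: dict(m) for r, m in raw["class_map_rule"].items()},
        noise_model=noise,
        lognormal_sigma=sigma,
        seed=int(raw.get("seed", 0)),
    )


# Marker signatures loosely mirroring the immune phenotypes resolvable in
# fetal intestine IMC: T cells (CD3+CD7+), innate lymphoid cells (CD3-CD7+),
# B cells (CD20+HLA-DR+), HLA-DR+ myeloid cells, CD163+ macrophages and
# E-cadherin+ epithelium. Counts are in the dynamic range of raw IMC pixels.
DEMO_SIGNATURES: dict[str, dict[str, float]] = {
    "T cell": {"CD45": 20.0, "CD3": 25.0, "CD7": 22.0},
    "ILC": {"CD45": 18.0, "CD7": 24.0, "CD161": 12.0, "CD69": 10.0},
    "B cell": {"CD45": 20.0, "CD20": 28.0, "HLA-DR": 15.0},
    "myeloid": {"CD45": 15.0, "HLA-DR": 24.0},
    "macrophage": {"CD45": 14.0, "CD163": 26.0, "HLA-DR": 18.0},
    "epithelium": {"E-cadherin": 30.0},
    "stroma": {"vimentin": 10.0},
}


# A 19-marker structural + immune panel typical of fetal-gut IMC acquisitions
IMC_PANEL_19: list[str] = [
    "CD45", "D2-40", "Collagen I", "aSMA", "CD31", "E-cadherin", "CD123",
    "CD7", "CD163", "CD20", "CD11c", "CD161", "Ki-67", "HLA-DR", "CD45RA",
    "CD3", "CD57", "vimentin", "CD56",
]

# Class signatures over the full panel (counts in raw IMC range)
ROI_SIGNATURES: dict[str, dict[str, float]] = {
    "stroma": {"vimentin": 12.0, "Collagen I": 15.0},
    "epithelium": {"E-cadherin": 30.0, "vimentin": 3.0},
    "vessel": {"CD31": 20.0, "aSMA": 15.0, "D2-40": 6.0},
    "T cell": {"CD45": 20.0, "CD3": 25.0, "CD7": 22.0, "CD45RA": 8.0},
    "ILC": {"CD45": 18.0, "CD7": 24.0, "CD161": 12.0, "CD56": 8.0, "CD57": 4.0},
    "B cell": {"CD45": 20.0, "CD20": 28.0, "HLA-DR": 15.0, "Ki-67": 4.0},
    "myeloid": {"CD45": 15.0, "HLA-DR": 24.0, "CD11c": 18.0, "CD123": 5.0},
    "macrophage": {"CD45": 14.0, "CD163": 26.0, "HLA-DR": 18.0, "CD11c": 10.0},
}


def roi_scale_spec(
    height: int = 500,
    width: int = 500,
    sigma: float = 0.3,
    seed: int = 0,
) -> SyntheticSpec:
    """A full acquisition-ROI-sized scene (default 500×500 = 2.5×10⁵ px)
    over the 19-marker panel: epithelium band, stromal bed with scattered
    immune cells and vessels, plus lymphoid-follicle discs."""
    band = height // 8
    lamina_mix = {
        "stroma": 0.45,
        "myeloid": 0.15,
        "macrophage": 0.15,
        "T cell": 0.1,
        "ILC": 0.1,
        "vessel": 0.05,
    }
    regions = [
        Region("epithelium_band", Rect(0, 0, band, width), "background", False),
        Region(
            "lamina_propria", Rect(band, 0, height - band, width), "background",
            False,
        ),
    ]
    rule: dict[str, dict[str, float]] = {
        "epithelium_band": {"epithelium": 1.0},
        "lamina_propria": lamina_mix,
    }
    radius = height / 12
    for i in range(3):
        name = f"LF{i + 1}"
        regions.append(
            Region(
                name,
                Disc(height * 0.45, width * (0.2 + 0.3 * i), radius),
                "LF",
                False,
            )
        )
        rule[name] = {"B cell": 0.35, "T cell": 0.3, "ILC": 0.25, "macrophage": 0.1}
    return SyntheticSpec(
        image_height=height,
        image_width=width,
        regions=regions,
        classes={c: dict(sig) for c, sig in ROI_SIGNATURES.items()},
        class_map_rule=rule,
        noise_model="lognormal",
        lognormal_sigma=sigma,
        seed=seed,
    )


def lf_quantification_spec(seed: int = 0) -> SyntheticSpec:
    """Seven follicle discs vs five control discs on a myeloid bed.

    The 7-vs-5 region design for CD161/CD69 double-positive pixel
    quantification: every follicle carries an ILC-rich core (CD161⁺CD69⁺),
    controls carry only sparse near-threshold signal, so control fractions
    are small, nonzero and untied.
    """
    h, w = 120, 220
    classes = {
        "ILC": {"CD45": 18.0, "CD161": 15.0, "CD69": 14.0},
        "myeloid": {"CD45": 15.0, "HLA-DR": 20.0, "CD161": 0.0, "CD69": 0.0},
        "myeloid_dim": {"CD45": 15.0, "HLA-DR": 20.0, "CD161": 6.0, "CD69": 6.0},
    }
    regions = [Region("bed", Rect(0, 0, h, w), "background", exclusive=False)]
    rule: dict[str, dict[str, float]] = {"bed": {"myeloid": 1.0}}
    centers = [(30 + 60 * (i // 6), 18 + 36 * (i % 6)) for i in range(12)]
    for i, (cy, cx) in enumerate(centers):
        radius = 8 + 0.15 * i  # distinct rasterized areas → untied fractions
        if i < 7:
            name, group = f"LF{i + 1}", "LF"
            rule[name] = {"ILC": 0.8 - 0.05 * i, "myeloid": 0.2 + 0.05 * i}
        else:
            name, group = f"ctrl{i - 6}", "non-LF"
            rule[name] = {"myeloid_dim": 1.0}
        regions.append(Region(name, Disc(cy, cx, radius), group, exclusive=False))
    return SyntheticSpec(
        image_height=h,
        image_width=w,
        regions=regions,
        classes=classes,
        class_map_rule=rule,
        noise_model="lognormal",
        lognormal_sigma=0.2,
        seed=seed,
    )


def demo_lf_spec(
    height: int = 96,
    width: int = 96,
    noise_model: str = "lognormal",
    sigma: float = 0.2,
    seed: int = 0,
) -> SyntheticSpec:
    """A small lymphoid-follicle-like scene: epithelium band, lamina propria
    rich in myeloid cells and macrophages, and an LF disc packed with B
    cells, T cells and ILCs, plus a matched non-LF control disc."""
    lf_r = height // 6
    regions = [
        Region(
            "epithelium_band", Rect(0, 0, height // 6, width), "background", False
        ),
        Region(
            "lamina_propria",
            Rect(height // 6, 0, height - height // 6, width),
            "background",
            False,
        ),
        Region(
            "LF1",
            Disc(height * 0.45, width * 0.3, lf_r),
            "LF",
            False,
        ),
        Region(
            "ctrl1",
            Disc(height * 0.45, width * 0.75, lf_r),
            "non-LF",
            False,
        ),
    ]
    # lamina propria: mostly stromal, with scattered immune cells; the
    # follicle is a dense lymphoid aggregate (B cells, T cells, ILCs)
    lamina_mix = {
        "stroma": 0.5,
        "myeloid": 0.15,
        "macrophage": 0.15,
        "T cell": 0.1,
        "ILC": 0.1,
    }
    rule = {
        "epithelium_band": {"epithelium": 1.0},
        "lamina_propria": lamina_mix,
        "LF1": {"B cell": 0.35, "T cell": 0.3, "ILC": 0.25, "macrophage": 0.1},
        "ctrl1": dict(lamina_mix),
    }
    return SyntheticSpec(
        image_height=height,
        image_width=width,
        regions=regions,
        classes=dict(DEMO_SIGNATURES),
        class_map_rule=rule,
        noise_model=noise_model,
        lognormal_sigma=sigma,
        seed=seed,
    )
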