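"""End-to-end pipeline: image → pixel table → hierarchy → embedding →
clusters → named classes → overlay → ROI quantification.

A single :class:`RunConfig` (loadable from YAML) drives every stage; all
randomness derives from its one seed, every artifact records the config
hash, and rerunning an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .gating import (
    DEFAULT_POSITIVITY_QUANTILE,
    DEFAULT_SIGNATURES,
    SignatureTable,
    assign_cell_types,
    cluster_embedding,
    expand_to_pixels,
)
from .hierarchy import (
    EmbedParams,
    WalkParams,
    build_hierarchy,
    build_knn_graph,
    embed_scale,
    save_hierarchy,
)
from .io import (
    read_group_table,
    read_multichannel_tiff,
    read_panel,
    read_roi_mask,
    write_overlay,
)
from .preprocess import DEFAULT_COFACTOR, DEFAULT_PERCENTILE, flatten, save_table
from .quantify import compare_groups, quantify_rois
from .render import DEFAULT_PALETTE, backproject

logger = logging.getLogger("pixplore")


def setup_logging(log_file: Path | None = None, verbose: bool = False) -> None:
    """Timestamped, leveled logging to stderr and optionally a run log."""
    logger.setLevel(logging.DEBUG)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setLevel(logging.DEBUG if verbose else logging.WARNING)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setLevel(logging.DEBUG)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with reproducibility metadata."""

    image: str
    panel: str
    out_dir: str
    roi_mask: str | None = None
    groups: str | None = None
    signatures: str | None = None  # None → built-in immune signature table
    # preprocessing
    markers: list[str] | None = None
    cofactor: float = DEFAULT_COFACTOR
    percentile: float = DEFAULT_PERCENTILE
    # hierarchy
    k: int = 30
    n_scales: int = 3
    seed: int = 0
    walk: WalkParams = field(default_factory=WalkParams)
    # embedding
    embed: EmbedParams = field(default_factory=EmbedParams)
    embed_scale_index: int | None = None  # None → top scale
    # gating
    bandwidth: float | None = None
    positivity_quantile: float = DEFAULT_POSITIVITY_QUANTILE
    # rendering
    base_marker: str | None = None
    # quantification
    marker_a: str | None = None
    marker_b: str | None = None
    group_a: str = "LF"
    group_b: str = "non-LF"
    direction: str = "greater"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "walk" in raw:
            raw["walk"] = WalkParams(**raw["walk"])
        if "embed" in raw:
            raw["embed"] = EmbedParams(**raw["embed"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("image", "panel", "roi_mask", "groups", "signatures"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: no such file: {p}")
        if (self.marker_a is None) != (self.marker_b is None):
            raise ValueError("marker_a and marker_b must be given together")


def _derive(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % 2**31)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the artifact set under ``config.out_dir``.

    Returns a name → path map of the written artifacts. Any stage failure
    propagates with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    setup_logging(out / "run.log")
    logger.info("pipeline start: config hash %s, seed %d", chash, config.seed)
    artifacts: dict[str, Path] = {"log": out / "run.log"}

    stage = "load"
    try:
        panel = read_panel(config.panel)
        stack = read_multichannel_tiff(config.image, panel)
        roi_set = None
        if config.roi_mask and config.groups:
            roi_set = read_roi_mask(config.roi_mask, read_group_table(config.groups))
        signatures = (
            SignatureTable.from_csv(config.signatures)
            if config.signatures
            else DEFAULT_SIGNATURES
        )

        stage = "preprocess"
        table = flatten(
            stack,
            markers=config.markers,
            cofactor=config.cofactor,
            percentile=config.percentile,
        )
        save_table(out / "pixel_table.npz", table, chash)
        artifacts["table"] = out / "pixel_table.npz"

        stage = "hierarchy"
        graph = build_knn_graph(table, k=config.k, seed=_derive(config.seed, 1))
        hierarchy = build_hierarchy(
            graph,
            n_scales=config.n_scales,
            walk_params=config.walk,
            seed=_derive(config.seed, 2),
        )
        save_hierarchy(out / "hierarchy.npz", hierarchy, chash)
        artifacts["hierarchy"] = out / "hierarchy.npz"

        stage = "embed"
        s = (
            config.embed_scale_index
            if config.embed_scale_index is not None
            else hierarchy.n_scales - 1
        )
        embedding = embed_scale(
            hierarchy, s, params=config.embed, seed=_derive(config.seed, 3)
        )
        np.savetxt(
            out / "embedding.csv",
            embedding.points,
            delimiter=",",
            header=f"x,y scale={s} config_hash={chash}",
        )
        artifacts["embedding"] = out / "embedding.csv"

        stage = "gate"
        clusters = cluster_embedding(embedding, bandwidth=config.bandwidth)
        labeling = expand_to_pixels(
            hierarchy, s, clusters, shape=stack.shape[1:]
        )
        labeling = assign_cell_types(
            labeling, table, signatures, config.positivity_quantile
        )
        import tifffile

        tifffile.imwrite(out / "label_map.tif", labeling.label_map.astype(np.int32))
        names_payload = json.dumps(
            {str(k): v for k, v in labeling.class_names.items()},
            indent=2,
            sort_keys=True,
        )
        (out / "class_names.json").write_text(names_payload)
        # companion file the standalone render/assign commands look for
        (out / "label_map.names.json").write_text(names_payload)
        artifacts["label_map"] = out / "label_map.tif"
        artifacts["class_names"] = out / "class_names.json"

        stage = "render"
        base = stack.channel(config.base_marker) if config.base_marker else None
        overlay = backproject(labeling, DEFAULT_PALETTE, base=base)
        write_overlay(out / "overlay.png", overlay)
        artifacts["overlay"] = out / "overlay.png"

        stage = "quantify"
        if roi_set is not None and config.marker_a and config.marker_b:
            results = quantify_rois(
                stack, config.marker_a, config.marker_b, list(roi_set)
            )
            lines = ["region\tgroup\tpositive_count\ttotal_count\tfraction"]
            for r in results:
                lines.append(
                    f"{r.region}\t{r.group}\t{r.positive_count}"
                    f"\t{r.total_count}\t{r.fraction:.6f}"
                )
            na = sum(1 for r in results if r.group == config.group_a)
            nb = sum(1 for r in results if r.group == config.group_b)
            if na >= 1 and nb >= 1:
                test = compare_groups(
                    results, config.group_a, config.group_b, config.direction
                )
                lines += [
                    f"# markers: {config.marker_a}+{config.marker_b}+",
                    f"# U={test.u} p_one_tailed={test.p_one_tailed:.6g} "
                    f"method={test.method} n1={test.n1} n2={test.n2} "
                    f"direction={config.group_a} {test.direction}",
                ]
            else:
                lines.append(
                    f"# no group comparison: {config.group_a} n={na}, "
                    f"{config.group_b} n={nb}"
                )
            lines.append(f"# config_hash={chash} seed={config.seed}")
            (out / "quantification.tsv").write_text("\n".join(lines) + "\n")
            artifacts["quantification"] = out / "quantification.tsv"
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "seed": config.seed,
                "version": __version__,
                "config": config.to_dict(),
                "artifacts": sorted(str(p.name) for p in artifacts.values()),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    artifacts["provenance"] = out / "provenance.json"
    logger.info("pipeline done: %d artifacts", len(artifacts))
    return artifacts


def write_demo_inputs(out_dir: str | Path, seed: int = 0) -> RunConfig:
    """Materialize the bundled synthetic follicle scene as pipeline inputs.

    Writes the multichannel image, panel table, ROI mask + group table and
    signature file, and returns a RunConfig wired to them.
    """
    from .io import write_group_table, write_multichannel_tiff, write_roi_mask
    from .synthetic import demo_lf_spec, generate_multiplex_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = demo_lf_spec(seed=seed)
    stack, gt = generate_multiplex_image(spec)
    write_multichannel_tiff(out / "image.tif", stack)
    from .io import write_panel

    write_panel(out / "panel.csv", stack.panel)
    write_roi_mask(out / "roi_mask.tif", gt.roi_set, shape=spec.shape)
    write_group_table(
        out / "groups.csv",
        {
            i + 1: (roi.name, roi.group)
            for i, roi in enumerate(gt.roi_set)
        },
    )
    with open(out / "signatures.csv", "w") as fh:
        fh.write("cell_type,positive,negative\n")
        fh.write("T cell,CD3 CD7,\n")
        fh.write("ILC,CD7,CD3\n")
        fh.write("B cell,CD20 HLA-DR,\n")
        fh.write("macrophage,CD163 HLA-DR,\n")
        fh.write("myeloid,HLA-DR,CD3 CD7 CD20 CD163\n")
        fh.write("epithelium,E-cadherin,\n")
    return RunConfig(
        image=str(out / "image.tif"),
        panel=str(out / "panel.csv"),
        roi_mask=str(out / "roi_mask.tif"),
        groups=str(out / "groups.csv"),
        signatures=str(out / "signatures.csv"),
        out_dir=str(out / "results"),
        seed=seed,
        marker_a="CD161",
        marker_b="CD69",
        base_marker="CD45",
    )
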