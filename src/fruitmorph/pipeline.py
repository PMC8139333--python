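"""End-to-end orchestration of the phenotyping pipeline.

Stages run in dependency order — segment, decalyx, phenotype (linear +
CIELAB), efd, gpa, shapes (VAE), color (AE), genetics — each reading only
its declared inputs and writing into its own subdirectory of the output
root.  A run manifest records per-stage outputs with content hashes, the
derived per-stage seeds and any warnings, so reruns with the same config
and seed are verifiable bit-for-bit for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import calyx as calyx_mod
from . import deep_color, deep_shape, efd, genetics, gpa, linear, segmentation

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

_STAGES = ["segment", "decalyx", "phenotype", "efd", "gpa", "shapes", "color", "genetics"]


@dataclass
class PipelineConfig:
    """All pipeline settings; round-trips losslessly through YAML."""

    input_dir: str = ""
    output_dir: str = ""
    stages: list[str] = field(default_factory=lambda: _STAGES.copy())
    seed: int = 0
    tile_size: int = 1000
    binarize_method: str = "mean"
    slic_segments: int = 60
    slic_compactness: float = 10.0
    efd_harmonics: int = 4
    gpa_landmarks: int = 50
    vae_epochs: int = 30
    vae_latent_dim: int = 8
    k_min: int = 2
    k_max: int = 9
    ae_epochs: int = 40
    mcmc_iterations: int = 20000
    mcmc_burn_in: int = 5000
    mcmc_thin: int = 10
    pedigree_csv: str = ""
    trait: str = "aspect"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: dict, stage: str, outputs: list[Path], seed: int, warns: list[str]) -> None:
    manifest["stages"][stage] = {
        "seed": seed,
        "outputs": {str(p): _sha256(p) for p in outputs},
        "warnings": warns,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"input directory {in_dir} does not exist")
    if "genetics" in config.stages:
        if not config.pedigree_csv or not Path(config.pedigree_csv).is_file():
            raise FileNotFoundError("genetics stage enabled but no pedigree CSV found")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    tiles_by_board: dict[str, list[segmentation.FruitTile]] = {}
    all_tiles: list[segmentation.FruitTile] = []

    def finish() -> dict:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    try:
        if "segment" in config.stages:
            seed = stage_seed(config.seed, "segment")
            seg_dir = out_dir / "tiles"
            seg_dir.mkdir(exist_ok=True)
            outputs, warns = [], []
            boards = sorted(in_dir.glob("*.png"))
            if not boards:
                raise FileNotFoundError(f"no board PNGs in {in_dir}")
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                for bpath in boards:
                    img = np.asarray(Image.open(bpath).convert("RGB"))
                    tiles = segmentation.segment_board(
                        img,
                        tile_size=config.tile_size,
                        method=config.binarize_method,
                        source=bpath.stem,
                    )
                    tiles_by_board[bpath.stem] = tiles
                    all_tiles.extend(tiles)
                if len(all_tiles) >= 2:
                    segmentation.classify_side(all_tiles, seed=seed)
                rows = []
                for tile in all_tiles:
                    gdir = seg_dir / tile.genotype / (tile.side or "unclassified")
                    gdir.mkdir(parents=True, exist_ok=True)
                    tpath = gdir / f"fruit_{tile.fruit_index}.png"
                    Image.fromarray(tile.pixels).save(tpath)
                    outputs.append(tpath)
                    rows.append(
                        {
                            "genotype": tile.genotype,
                            "side": tile.side,
                            "tile": str(tpath.relative_to(out_dir)),
                            "area": int(tile.fruit_mask.sum()),
                        }
                    )
                mpath = seg_dir / "manifest.csv"
                pd.DataFrame(rows).to_csv(mpath, index=False)
                outputs.append(mpath)
            warns = sorted({str(w.message) for w in wlist})
            _record(manifest, "segment", outputs, seed, warns)

        external = [t for t in all_tiles if t.side != "internal"]
        internal = [t for t in all_tiles if t.side == "internal"]

        masks: list[np.ndarray] = []
        if "decalyx" in config.stages:
            seed = stage_seed(config.seed, "decalyx")
            for tile in external:
                spmap = calyx_mod.slic_segment(
                    tile, n_segments=config.slic_segments, compactness=config.slic_compactness
                )
                masks.append(calyx_mod.central_superpixel_mask(spmap, tile))
            _record(manifest, "decalyx", [], seed, [])
        else:
            masks = [t.fruit_mask for t in external]

        contours = [linear.trace_contour(m) for m in masks] if external else []

        if "phenotype" in config.stages:
            seed = stage_seed(config.seed, "phenotype")
            rows = []
            for tile, mask in zip(external, masks):
                rec = linear.descriptors(mask).as_dict()
                rec.update(linear.lab_stats(tile).as_dict())
                rec.update(genotype=tile.genotype, fruit_index=tile.fruit_index)
                rows.append(rec)
            ppath = out_dir / "descriptors.csv"
            pd.DataFrame(rows).to_csv(ppath, index=False)
            _record(manifest, "phenotype", [ppath], seed, [])

        if "efd" in config.stages and contours:
            seed = stage_seed(config.seed, "efd")
            sets = [
                efd.efd_normalize(efd.efd_decompose(c, n_harmonics=config.efd_harmonics))
                for c in contours
            ]
            cols = [f"{n}{i}" for i in range(1, config.efd_harmonics + 1) for n in "abcd"]
            df = pd.DataFrame([s.flat() for s in sets], columns=cols)
            df.insert(0, "genotype", [t.genotype for t in external])
            epath = out_dir / "efd.csv"
            df.to_csv(epath, index=False)
            _record(manifest, "efd", [epath], seed, [])

        if "gpa" in config.stages and len(contours) >= 2:
            seed = stage_seed(config.seed, "gpa")
            configs = [
                gpa.radial_landmarks(gpa.orient_contour(c), k=config.gpa_landmarks)
                for c in contours
            ]
            res = gpa.gpa_align(configs)
            lpath = out_dir / "landmarks.csv"
            flat = res.aligned.reshape(len(configs), -1)
            pd.DataFrame(flat).assign(genotype=[t.genotype for t in external]).to_csv(
                lpath, index=False
            )
            spath = out_dir / "landmark_sd.csv"
            pd.DataFrame({"landmark": range(config.gpa_landmarks), "sd": res.per_landmark_sd}).to_csv(
                spath, index=False
            )
            _record(manifest, "gpa", [lpath, spath], seed, [])

        if "shapes" in config.stages and external:
            seed = stage_seed(config.seed, "shapes")
            if len(external) < 50:
                _record(
                    manifest,
                    "shapes",
                    [],
                    seed,
                    [f"skipped: {len(external)} external tiles, VAE training needs >= 50"],
                )
            else:
                from skimage.transform import resize

                sils = np.stack(
                    [
                        resize(m.astype(float), (64, 64), order=0, anti_aliasing=False)
                        for m in masks
                    ]
                )
                spec = deep_shape.VAESpec(latent_dim=config.vae_latent_dim)
                model, emb, _ = deep_shape.train_vae(
                    sils, spec, epochs=config.vae_epochs, seed=seed
                )
                clustering = deep_shape.select_k(emb, config.k_min, config.k_max, seed=seed)
                cpath = out_dir / "shape_clusters.csv"
                pd.DataFrame(
                    {
                        "genotype": [t.genotype for t in external],
                        "cluster": clustering.labels,
                    }
                ).to_csv(cpath, index=False)
                manifest["best_k"] = clustering.best_k
                _record(manifest, "shapes", [cpath], seed, [])

        if "color" in config.stages and internal:
            seed = stage_seed(config.seed, "color")
            from skimage.transform import resize

            small = [
                (resize(t.pixels, (64, 64), order=1, preserve_range=True)).astype(np.uint8)
                for t in internal
            ]
            rows = []
            if len(small) >= 20:
                model, _ = deep_color.train_denoiser(small, epochs=config.ae_epochs, seed=seed)
                small = [deep_color.denoise(model, s) for s in small]
            for tile, s in zip(internal, small):
                prof = deep_color.color_profile(s, seed=seed)
                row = {f"pct_{k}": v for k, v in prof.percent.items()}
                row.update(genotype=tile.genotype, n_fruit_px=prof.n_fruit_px)
                rows.append(row)
            cpath = out_dir / "colors.csv"
            pd.DataFrame(rows).to_csv(cpath, index=False)
            _record(manifest, "color", [cpath], seed, [])

        if "genetics" in config.stages:
            seed = stage_seed(config.seed, "genetics")
            ped = genetics.Pedigree.from_csv(config.pedigree_csv)
            df = pd.read_csv(out_dir / "descriptors.csv")
            model = genetics.VarianceComponentsModel.from_dataframe(df, config.trait, ped)
            res = model.fit(
                iterations=config.mcmc_iterations,
                burn_in=config.mcmc_burn_in,
                thin=config.mcmc_thin,
                seed=seed,
            )
            gpath = out_dir / "genetics.json"
            gpath.write_text(
                json.dumps(
                    {
                        "trait": config.trait,
                        "posterior_means": res.posterior_means.to_dict(),
                        "h2_a": res.h2_a,
                        "h2_d": res.h2_d,
                    },
                    indent=2,
                )
            )
            _record(manifest, "genetics", [gpath], seed, [])
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        finish()
        raise
    return finish()
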