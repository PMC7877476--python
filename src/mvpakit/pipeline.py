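"""End-to-end pipeline orchestration and a thin command-line interface.

A single :class:`PipelineConfig` drives simulate -> (glm) -> decode -> group
-> report.  All randomness flows from one master seed through named per-stage
substreams, so a rerun with the same config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior, cohort, decoding, design, group
from .searchlight import SphereSpec

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "cli"]

log = logging.getLogger("mvpakit")


@dataclass
class PipelineConfig:
    """Nested configuration for an end-to-end synthetic run."""

    seed: int = 0
    outdir: str = "mvpakit_out"
    n_subjects: int = 30
    group_sizes: tuple[int, int, int] = (10, 10, 10)
    grid: tuple[int, int, int] = (20, 24, 20)
    noise_sd: float = 1.0
    radius: float = 4.0
    costs: tuple[float, ...] = (0.1, 1.0, 10.0)
    levels: tuple[str, ...] = ("category", "subcategory")
    fwhm_mm: float = 6.0
    voxel_alpha: float = 0.05
    cluster_forming_p: float = 0.001
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    use_bold_glm: bool = False  # render BOLD + fit the GLM instead of betas

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        for k in ("group_sizes", "grid", "costs", "levels"):
            if k in d:
                d[k] = tuple(d[k])
        return PipelineConfig(**d)

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = (json.loads(text) if str(path).endswith(".json")
             else yaml.safe_load(text))
        return PipelineConfig.from_dict(d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Derive a named substream seed (< 2**31) from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig, stages=("simulate", "decode",
                                                 "group")) -> dict:
    """Execute the requested stages; returns a manifest of results.

    The manifest maps stage names to in-memory results and, when an output
    directory is set, records the files written along with the config hash.
    """
    manifest: dict = {"config_hash": config.hash(), "stages": list(stages),
                      "artifacts": {}}
    geometry = cohort.VolumeGeometry(shape=config.grid)
    regions = cohort.default_regions(geometry)
    scheme = design.CategoryScheme()
    schedule = design.make_schedule(seed=stage_seed(config.seed, "schedule"))
    profiles = cohort.sample_cohort(config.n_subjects, config.group_sizes,
                                    seed=stage_seed(config.seed, "cohort"))
    bank = cohort.build_pattern_bank(geometry, regions, scheme,
                                     seed=stage_seed(config.seed, "patterns"))
    manifest["schedule"] = schedule
    manifest["profiles"] = profiles
    manifest["regions"] = regions
    manifest["geometry"] = geometry

    beh_scores = {}
    beta_series = {}
    if "simulate" in stages:
        for i, prof in enumerate(profiles):
            log.info("simulate %s", prof.subject_id)
            rec = cohort.simulate_behavior(
                prof, schedule, task="category",
                seed=stage_seed(config.seed, "behavior", i))
            beh_scores[prof.subject_id] = behavior.performance(rec)
            if config.use_bold_glm:
                from . import glm as glm_mod
                bold = cohort.render_bold_runs(
                    prof, schedule, bank, regions, geometry,
                    noise_sd=config.noise_sd,
                    seed=stage_seed(config.seed, "bold", i))
                n_vol = bold.runs[0].shape[0] - bold.n_dummy_volumes
                designs = [glm_mod.build_design_matrix(
                    schedule.run_entries(r), n_vol, bold.tr,
                    motion=bold.motion[r - 1][bold.n_dummy_volumes:])
                    for r in range(1, schedule.n_runs + 1)]
                beta_series[prof.subject_id] = glm_mod.fit_glm(
                    bold, designs, schedule)
            else:
                beta_series[prof.subject_id] = cohort.render_beta_series(
                    prof, schedule, bank, regions, geometry,
                    noise_sd=config.noise_sd,
                    seed=stage_seed(config.seed, "betas", i))
        manifest["behavior"] = beh_scores

    if "decode" in stages:
        spec = SphereSpec(radius=config.radius)
        maps: dict[str, dict[str, decoding.AccuracyMap]] = {
            lvl: {} for lvl in config.levels}
        for i, prof in enumerate(profiles):
            for lvl in config.levels:
                log.info("decode %s level=%s", prof.subject_id, lvl)
                cfg = decoding.DecodingConfig.for_level(
                    lvl, costs=tuple(config.costs))
                maps[lvl][prof.subject_id] = decoding.decode_whole_brain(
                    beta_series[prof.subject_id], spec, cfg,
                    subject_id=prof.subject_id)
        manifest["accuracy_maps"] = maps

    if "group" in stages:
        gcfg = group.GroupConfig(
            fwhm_mm=config.fwhm_mm,
            voxel_alpha=config.voxel_alpha,
            cluster_forming_p=config.cluster_forming_p,
            cluster_alpha=config.cluster_alpha,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "group"))
        results = {}
        order = [p.subject_id for p in profiles]
        scores = [beh_scores[s] for s in order]
        for lvl in config.levels:
            log.info("group level=%s", lvl)
            amaps = [manifest["accuracy_maps"][lvl][s].data for s in order]
            chance = manifest["accuracy_maps"][lvl][order[0]].chance
            results[lvl] = group.run_group_analysis(
                amaps, scores, chance, geometry.mask, gcfg)
        manifest["group_results"] = results

    if config.outdir:
        _write_artifacts(config, manifest)
    return manifest


def _write_artifacts(config: PipelineConfig, manifest: dict) -> None:
    from . import io as mio

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = manifest["geometry"]
    design.write_events_tsv(manifest["schedule"], out / "events.tsv")
    mio.save_mask(geometry.mask, out / "mask.nii.gz")
    if "behavior" in manifest:
        df = cohort.cohort_to_frame(
            manifest["profiles"],
            {s: {"beh_category": v} for s, v in manifest["behavior"].items()})
        df.to_csv(out / "cohort.tsv", sep="\t", index=False)
    for lvl, subj_maps in manifest.get("accuracy_maps", {}).items():
        for sid, amap in subj_maps.items():
            mio.save_accuracy_map(
                amap, out / f"{sid}_{lvl}_accuracy.nii.gz",
                out / f"{sid}_{lvl}_accuracy.json")
    for lvl, res in manifest.get("group_results", {}).items():
        res.cluster_table.to_csv(out / f"group_{lvl}_clusters.tsv",
                                 sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps({
        "config": config.to_dict(), "config_hash": manifest["config_hash"],
        "stages": manifest["stages"],
    }, indent=1))
    manifest["artifacts"]["outdir"] = str(out)


def save_report_png(manifest: dict, path) -> None:
    """Orthogonal-slice PNG of the group t-map and significance masks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lvl = next(iter(manifest["group_results"]))
    res = manifest["group_results"][lvl]
    t = res.t_map
    cx, cy, cz = [s // 2 for s in t.shape]
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, sl in zip(axes, (t[cx], t[:, cy], t[:, :, cz])):
        ax.imshow(sl.T, origin="lower", cmap="hot")
        ax.axis("off")
    fig.suptitle(f"group t-map ({lvl})")
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# CLI: thin wrappers over the library
# ---------------------------------------------------------------------------

import click


@click.group()
def cli():
    """Searchlight MVPA pipeline: simulate, decode, group-level inference."""
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


def _load_config(config_path, seed, outdir) -> PipelineConfig:
    cfg = (PipelineConfig.from_file(config_path) if config_path
           else PipelineConfig())
    if seed is not None:
        cfg.seed = seed
    if outdir is not None:
        cfg.outdir = outdir
    return cfg


_opts = [
    click.option("--config", "config_path", type=click.Path(exists=True),
                 default=None, help="YAML or JSON pipeline config."),
    click.option("--seed", type=int, default=None),
    click.option("--outdir", type=click.Path(), default=None),
]


def _with_opts(f):
    for opt in reversed(_opts):
        f = opt(f)
    return f


@cli.command()
@_with_opts
def simulate(config_path, seed, outdir):
    """Generate the synthetic cohort (betas, behavior, mask, events)."""
    run_pipeline(_load_config(config_path, seed, outdir), stages=("simulate",))


@cli.command()
@_with_opts
def all(config_path, seed, outdir):
    """Run simulate -> decode -> group end to end."""
    run_pipeline(_load_config(config_path, seed, outdir))


@cli.command()
@_with_opts
def report(config_path, seed, outdir):
    """Run the full pipeline and render an orthogonal-slice PNG."""
    cfg = _load_config(config_path, seed, outdir)
    manifest = run_pipeline(cfg)
    out = Path(cfg.outdir) / "report.png"
    save_report_png(manifest, out)
    click.echo(f"report written to {out}")


@cli.command()
@click.option("--betas", required=True, type=click.Path(exists=True))
@click.option("--labels", required=True, type=click.Path(exists=True))
@click.option("--mask", "mask_path", type=click.Path(exists=True))
@click.option("--level", type=click.Choice(["category", "subcategory"]),
              default="category")
@click.option("--radius", type=float, default=4.0)
@click.option("--costs", default="0.1,1,10")
@click.option("--out", "out_path", type=click.Path(), default="accuracy.nii.gz")
def decode(betas, labels, mask_path, level, radius, costs, out_path):
    """Whole-brain searchlight decoding of one subject's beta series."""
    from . import io as mio

    bs = mio.load_beta_series(betas, labels, mask_path)
    cfg = decoding.DecodingConfig.for_level(
        level, costs=tuple(float(c) for c in costs.split(",")))
    amap = decoding.decode_whole_brain(bs, SphereSpec(radius=radius), cfg)
    mio.save_accuracy_map(amap, out_path, str(out_path) + ".json")
    click.echo(f"mean in-mask accuracy {np.nanmean(amap.values):.3f} "
               f"(chance {amap.chance:.4f})")


@cli.command(name="group")
@click.option("--maps", "maps_dir", required=True, type=click.Path(exists=True))
@click.option("--cohort", "cohort_tsv", required=True,
              type=click.Path(exists=True))
@click.option("--mask", "mask_path", required=True, type=click.Path(exists=True))
@click.option("--chance", type=float, required=True)
@click.option("--fwhm", type=float, default=6.0)
@click.option("--alpha", type=float, default=0.05)
@click.option("--forming-p", type=float, default=0.001)
@click.option("--nperm", type=int, default=1000)
@click.option("--seed", type=int, default=0)
@click.option("--score-column", default="beh_category")
@click.option("--out", "out_tsv", type=click.Path(), default="clusters.tsv")
def group_cmd(maps_dir, cohort_tsv, mask_path, chance, fwhm, alpha,
              forming_p, nperm, seed, score_column, out_tsv):
    """Second-level analysis over per-subject accuracy map NIfTIs."""
    import pandas as pd

    from . import io as mio

    mask = mio.load_mask(mask_path)
    tab = pd.read_csv(cohort_tsv, sep="\t")
    maps, scores = [], []
    for _, row in tab.iterrows():
        hits = sorted(Path(maps_dir).glob(f"{row.subject_id}_*accuracy.nii.gz"))
        if not hits:
            raise click.ClickException(f"no map for {row.subject_id}")
        maps.append(np.asarray(nib_load(hits[0])))
        scores.append(row[score_column])
    cfg = group.GroupConfig(fwhm_mm=fwhm, voxel_alpha=alpha,
                            cluster_forming_p=forming_p, cluster_alpha=alpha,
                            n_perm=nperm, seed=seed)
    res = group.run_group_analysis(maps, scores, chance, mask, cfg)
    res.cluster_table.to_csv(out_tsv, sep="\t", index=False)
    click.echo(f"{int(res.accuracy_sig.sum())} accuracy-significant voxels; "
               f"conjunction fraction {res.conjunction_fraction:.4f}")


def nib_load(path):
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
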