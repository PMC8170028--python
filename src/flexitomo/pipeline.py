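"""End-to-end pipeline orchestration with resumable stages.

A run is driven by a single YAML (or dict) configuration with one shared
rendering block consumed by both the simulator and the aligner, a mandatory
seed for every stochastic stage, and a manifest recording the configuration
hash so re-runs are idempotent and ``resume`` can skip completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import structures, nma, tomosim, align as align_mod, confspace, phantoms

logger = logging.getLogger("flexitomo")

STAGES = ("reference", "nma", "simulate", "align", "space", "average")

DEFAULT_CONFIG = {
    "seed": 0,
    "run_dir": "flexitomo_run",
    "reference": {"kind": "synthetic", "n_atoms": 1656, "path": None, "chain": None,
                  "pseudoatom_sigma": 1.0, "target_error": 0.05},
    "rendering": {"box": 64, "voxel_size": 2.2, "sigma": None},
    "nma": {"method": "auto", "cutoff": 8.0, "cutoff_percentile": 0.01,
            "residues_per_block": 2, "n_modes": 12,
            "n_lowest": 3, "min_collectivity": 0.0, "extra_modes": []},
    "simulate": {"kind": "Discrete", "n": 12, "snr": 0.01, "defocus_um": -1.0,
                 "tilt_range": [-60.0, 60.0], "tilt_step": 1.0,
                 "shift_range": 5.0, "noise_split": 0.5},
    "align": {"trust_region_scale": 1.0, "max_iterations": 60,
              "final_radius": 1.0, "coarse_step": 20.0, "fine_step": 1.0,
              "max_shift": 8.0, "max_frequency": 0.25, "ctf_match": True,
              "workers": 1},
    "space": {"dims": 2, "p_threshold": 0.01},
    "average": {"wedge_fill": True},
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}) or {})
        else:
            out[k] = override.get(k, v)
    for k in override:
        if k not in out:
            out[k] = override[k]
    return out


def load_config(source) -> dict:
    """Normalize a YAML path or dict into a full configuration."""
    import yaml

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source or {})
    return _merge(DEFAULT_CONFIG, cfg)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _alignment_options(cfg: dict, ctf) -> align_mod.AlignmentOptions:
    a = cfg["align"]
    return align_mod.AlignmentOptions(
        trust_region_scale=a["trust_region_scale"],
        max_iterations=a["max_iterations"],
        final_radius=a["final_radius"],
        coarse_step=a["coarse_step"],
        fine_step=a["fine_step"],
        max_shift=a["max_shift"],
        max_frequency=a["max_frequency"],
        render_sigma=cfg["rendering"]["sigma"],
        ctf=ctf if a["ctf_match"] else None,
    )


def run_pipeline(config, resume: bool = False) -> Path:
    """Execute the full workflow; returns the run directory.

    Stages: reference loading (with pseudoatomization for density maps),
    normal-mode analysis, subtomogram simulation (or loading), combined
    elastic/rigid alignment, conformational-space construction, and global
    averaging.  With ``resume`` stages whose outputs already exist under the
    run directory (from the same configuration) are skipped.
    """
    cfg = load_config(config)
    run_dir = Path(cfg["run_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") != h:
            if resume:
                raise ValueError("cannot resume: configuration changed")
            manifest = {"config_hash": h, "stages": {}}
    else:
        manifest = {"config_hash": h, "stages": {}}
    manifest.update(config_hash=h, seed=cfg["seed"],
                    versions={"flexitomo": _version(), "numpy": np.__version__})
    (run_dir / "config.yaml").write_text(_dump_yaml(cfg))

    def stage_done(name):
        return resume and manifest["stages"].get(name, {}).get("done", False)

    def finish(name, **info):
        manifest["stages"][name] = {"done": True, "time": time.time(), **info}
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    rend = cfg["rendering"]
    box, voxel = int(rend["box"]), float(rend["voxel_size"])

    # ---- reference -------------------------------------------------------
    ref_cfg = cfg["reference"]
    t0 = time.time()
    if ref_cfg["kind"] == "synthetic":
        ref = phantoms.make_globular_structure(
            n_atoms=int(ref_cfg["n_atoms"]), seed=int(cfg["seed"]))
    elif ref_cfg["kind"] == "pdb":
        ref = structures.read_pdb(ref_cfg["path"], chain=ref_cfg["chain"])
        ref = ref.centered()
    elif ref_cfg["kind"] == "mrc":
        vol = structures.read_mrc(ref_cfg["path"])
        ref = structures.pseudoatomize(
            vol, sigma=float(ref_cfg["pseudoatom_sigma"]),
            target_error=float(ref_cfg["target_error"]))
    else:
        raise ValueError(f"unknown reference kind {ref_cfg['kind']!r}")
    structures.write_pdb(run_dir / "reference.pdb", ref)
    logger.info("reference: %d nodes (%.1fs)", ref.n_atoms, time.time() - t0)
    finish("reference", n_atoms=ref.n_atoms)

    # ---- normal modes ----------------------------------------------------
    modes_dir = run_dir / "modes"
    ncfg = cfg["nma"]
    if stage_done("nma") and (modes_dir / "modes.tsv").exists():
        ms = nma.load_modes(modes_dir)
    else:
        t0 = time.time()
        method = ncfg["method"]
        if method == "auto":
            method = "cartesian" if isinstance(ref, structures.PseudoatomModel) \
                else "rtb"
        if method == "rtb":
            ms = nma.compute_modes_rtb(
                ref, residues_per_block=int(ncfg["residues_per_block"]),
                cutoff=float(ncfg["cutoff"]), n_modes=int(ncfg["n_modes"]))
        else:
            cutoff = ncfg["cutoff"]
            if isinstance(ref, structures.PseudoatomModel):
                cutoff = nma.pseudoatom_cutoff(
                    ref.coords, float(ncfg["cutoff_percentile"]))
            ms = nma.compute_modes_cartesian(
                nma.ElasticNetwork(ref.coords, float(cutoff)),
                n_modes=int(ncfg["n_modes"]))
        nma.save_modes(ms, modes_dir)
        logger.info("nma (%s): %d modes (%.1fs)", method, ms.n_modes,
                    time.time() - t0)
        finish("nma", method=method)
    sel = nma.select_modes(ms, int(ncfg["n_lowest"]),
                           float(ncfg["min_collectivity"]),
                           tuple(ncfg["extra_modes"]))

    # ---- simulation ------------------------------------------------------
    sim = cfg["simulate"]
    ctf = tomosim.CTFParams(defocus_um=float(sim["defocus_um"]))
    sub_dir = run_dir / "subtomograms"
    truth_path = run_dir / "ground_truth.tsv"
    if stage_done("simulate") and truth_path.exists():
        subs, records = _load_dataset(sub_dir, truth_path, sim)
    else:
        t0 = time.time()
        subs, records = tomosim.generate_dataset(
            ref, ms, sim["kind"], int(sim["n"]), box=box, voxel_size=voxel,
            snr=float(sim["snr"]), ctf=ctf,
            tilt_range=tuple(sim["tilt_range"]), tilt_step=float(sim["tilt_step"]),
            shift_range=float(sim["shift_range"]), sigma=rend["sigma"],
            noise_split=float(sim["noise_split"]), seed=int(cfg["seed"]))
        sub_dir.mkdir(exist_ok=True)
        for i, s in enumerate(subs):
            structures.write_mrc(sub_dir / f"subtomo_{i:05d}.mrc", s.volume)
        table = tomosim.records_to_table(records)
        table["filename"] = [f"subtomo_{i:05d}.mrc" for i in range(len(subs))]
        table.to_csv(truth_path, sep="\t", index=False)
        logger.info("simulate: %d subtomograms (%.1fs)", len(subs),
                    time.time() - t0)
        finish("simulate", n=len(subs))

    # ---- alignment -------------------------------------------------------
    align_path = run_dir / "alignment.tsv"
    t0 = time.time()
    table = align_mod.align_dataset(
        ref, ms, sel, subs, _alignment_options(cfg, ctf),
        workers=int(cfg["align"]["workers"]),
        checkpoint=align_path if resume else None)
    table.to_csv(align_path, sep="\t", index=False)
    logger.info("align: %d items (%.1fs)", len(table), time.time() - t0)
    finish("align", n=len(table))

    # ---- conformational space -------------------------------------------
    sp_cfg = cfg["space"]
    amp_cols = [f"a{m}" for m in sel.indices]
    amps = table[amp_cols].to_numpy()
    space = confspace.pca_fit_project(amps, d=int(sp_cfg["dims"]),
                                      ccc=table["ccc"].to_numpy())
    space.inlier, space.p_values = confspace.mahalanobis_filter(
        amps, float(sp_cfg["p_threshold"]))
    confspace.save_space(space, run_dir / "space.tsv")
    confspace.plot_space(space, run_dir / "space.png")
    finish("space", inliers=int(space.inlier.sum()))

    # ---- global average --------------------------------------------------
    rigids = [tomosim.RigidParams((r["rot"], r["tilt"], r["psi"]),
                                  (r["x"], r["y"], r["z"]))
              for _, r in table.iterrows()]
    keep = [i for i in range(len(subs)) if space.inlier[i]]
    global_avg = confspace.average_group(subs, rigids, keep or None)
    structures.write_mrc(run_dir / "global_average.mrc", global_avg)
    if cfg["average"]["wedge_fill"]:
        filled = confspace.average_group(subs, rigids, keep or None,
                                         wedge_fill=True,
                                         global_average=global_avg)
        structures.write_mrc(run_dir / "global_average_filled.mrc", filled)
    finish("average", n=len(keep))
    return run_dir


def _load_dataset(sub_dir: Path, truth_path: Path, sim: dict):
    import pandas as pd

    table = pd.read_csv(truth_path, sep="\t")
    wedge = tomosim.WedgeDescriptor(*sim["tilt_range"])
    subs, records = [], []
    amp_cols = [c for c in table.columns if c.startswith("a") and c[1:].isdigit()]
    for _, row in table.iterrows():
        vol = structures.read_mrc(sub_dir / row["filename"])
        subs.append(tomosim.Subtomogram(vol, wedge))
        records.append(tomosim.GroundTruthRecord(
            amplitudes=row[amp_cols].to_numpy(dtype=float),
            mode_numbers=tuple(int(c[1:]) for c in amp_cols),
            rigid=tomosim.RigidParams((row["rot"], row["tilt"], row["psi"]),
                                      (row["x"], row["y"], row["z"])),
            label=str(row["label"])))
    return subs, records


def _version() -> str:
    from . import __version__

    return __version__


def _dump_yaml(cfg: dict) -> str:
    import yaml

    return yaml.safe_dump(cfg, sort_keys=False)
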