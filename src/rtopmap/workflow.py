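"""Configuration-driven orchestration of the synthetic end-to-end pipeline.

Stages (``simulate``, ``rtop``, ``parcel-stats``, ``gradients``,
``connectivity``, ``cca``) each generate their own phantom inputs with
known ground truth, run the corresponding estimator, write standard-format
outputs (NIfTI/GIFTI/CSV/JSON) under the configured output directory, and
append a manifest entry (config hash + output checksums).  ``run_all``
executes every stage and emits a report comparing recovered quantities to
planted truths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bb
from . import connectivity as conn
from . import gradients as gr
from . import io as rio
from . import mapbasis as mb
from . import surface as sf
from . import synthetic as syn
from .scheme import make_acquisition_scheme

log = logging.getLogger("rtopmap")

STAGES = ("simulate", "rtop", "parcel-stats", "gradients", "connectivity", "cca")

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]


@dataclass
class PipelineConfig:
    """All tunables of the synthetic pipeline; every stochastic stage has an
    explicit seed derived from ``seed`` + a fixed stage offset."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # acquisition / reconstruction
    b_values: tuple[float, ...] = (1000.0, 2000.0, 3000.0)
    dirs_per_shell: int = 90
    n_b0: int = 6
    small_delta_ms: float = 10.0
    big_delta_ms: float = 43.0
    radial_order: int = 6
    regularization: float | str = "gcv"
    free_diffusivity: float = mb.FREE_WATER_DIFFUSIVITY
    n_rtop_voxels: int = 20
    snr: float | None = None
    # surface statistics
    n_subjects: int = 60
    stability_sample_sizes: tuple[int, ...] = (10, 15, 20, 25, 50)
    stability_resamples: int = 100
    stability_alpha: float = 0.01
    stability_criterion: float = 0.95
    # gradients
    n_gradient_subjects: int = 50
    gradient_direction: tuple[float, float, float] = (0.8, 0.6, 0.0)
    gradient_noise_sd: float = 0.05
    # connectivity
    n_rest_subjects: int = 12
    rest_grid: tuple[int, int, int] = (20, 12, 8)
    rest_timepoints: int = 240
    rest_tr: float = 0.72
    rest_coupling: float = 0.6
    connectivity_alpha: float = 0.01
    # brain-behavior
    n_cca_subjects: int = 413
    planted_canonical_r: float = 0.32
    missing_fraction: float = 0.015

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for key in ("b_values", "stability_sample_sizes", "gradient_direction",
                    "rest_grid"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def hash(self) -> str:
        enc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGES.index(stage)) % (2**31 - 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest_entry(cfg: PipelineConfig, stage: str, outputs: list[Path]) -> None:
    out = Path(cfg.out_dir)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "config_hash": cfg.hash(), "stages": {},
    }
    manifest["stages"][stage] = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {str(p.relative_to(out)): _checksum(p) for p in outputs},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig) -> dict:
    """Write every phantom input in its on-disk format."""
    out = Path(cfg.out_dir) / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("simulate")
    scheme = make_acquisition_scheme(
        list(cfg.b_values), cfg.dirs_per_shell, cfg.n_b0,
        cfg.small_delta_ms, cfg.big_delta_ms, seed=seed,
    )
    rng = np.random.default_rng(seed)
    mixtures = [syn.random_mixture(rng) for _ in range(cfg.n_rtop_voxels)]
    signals = np.stack([
        syn.simulate_voxel_signal(scheme, m, snr=cfg.snr, seed=seed + i)
        for i, m in enumerate(mixtures)
    ])
    side = int(np.ceil(cfg.n_rtop_voxels ** (1 / 3)))
    vol = np.zeros((side, side, side, scheme.n_measurements), dtype=np.float32)
    vol.reshape(-1, scheme.n_measurements)[: cfg.n_rtop_voxels] = signals
    rio.save_dmri(out / "dmri.nii.gz", vol, scheme)
    oracle = np.array([syn.rtop_oracle(m, scheme.tau) for m in mixtures])
    np.savetxt(out / "rtop_oracle.txt", oracle)

    phantom = syn.make_surface_phantom(
        gradient_direction=np.asarray(cfg.gradient_direction),
        noise_sd=cfg.gradient_noise_sd, seed=seed,
    )
    for h in ("L", "R"):
        rio.save_surface(out / f"insula_{h}.surf.gii", phantom.meshes[h])
        rio.save_labels(out / f"insula_{h}.label.gii", phantom.labels[h])

    rest = syn.make_rest_phantom(cfg.rest_grid, cfg.rest_timepoints,
                                 cfg.rest_tr, cfg.rest_coupling, seed=seed)
    rio.save_volume(out / "rest.nii.gz", rest.data, np.eye(4), units="a.u.")
    rio.save_motion(out / "rest_motion.txt", rest.motion_params)

    bbp = syn.make_brain_behavior(cfg.n_cca_subjects, cfg.planted_canonical_r,
                                  cfg.missing_fraction, seed=seed)
    pd.DataFrame(bbp.behavior, columns=bbp.behavior_columns).assign(
        subject=bbp.subject_ids
    ).to_csv(out / "behavior.csv", index=False)

    outputs = sorted(out.iterdir())
    _manifest_entry(cfg, "simulate", outputs)
    return {"scheme_measurements": scheme.n_measurements, "tau_s": scheme.tau,
            "n_voxels": cfg.n_rtop_voxels, "outputs": [str(p) for p in outputs]}


def _stage_rtop(cfg: PipelineConfig) -> dict:
    """Fit the MAP basis on the simulated voxels; compare to the oracle."""
    out = Path(cfg.out_dir) / "rtop"
    out.mkdir(parents=True, exist_ok=True)
    sim = Path(cfg.out_dir) / "simulate"
    if not (sim / "dmri.nii.gz").exists():
        raise FileNotFoundError(f"missing stage input: {sim / 'dmri.nii.gz'}")
    data, affine, scheme = rio.load_dmri(sim / "dmri.nii.gz")
    oracle = np.loadtxt(sim / "rtop_oracle.txt")
    n_vox = oracle.size
    signals = data.reshape(-1, scheme.n_measurements)[:n_vox]
    fit = mb.fit_map_basis(signals, scheme, cfg.radial_order, cfg.regularization)
    rtop = mb.rtop_from_fit(fit)
    norm = mb.normalize_rtop(rtop, cfg.free_diffusivity, scheme.tau)
    norm_oracle = mb.normalize_rtop(oracle, cfg.free_diffusivity, scheme.tau)

    shape = data.shape[:3]
    vol = np.full(np.prod(shape), np.nan)
    vol[:n_vox] = norm
    rio.save_volume(out / "normalized_rtop.nii.gz", vol.reshape(shape), affine,
                    units="dimensionless")
    rel_err = np.abs(norm - norm_oracle) / norm_oracle
    report = {
        "median_relative_error": float(np.median(rel_err)),
        "max_relative_error": float(rel_err.max()),
        "mean_normalized_rtop": float(norm.mean()),
        "n_nonpositive_flagged": int(np.sum(rtop <= 0)),
    }
    rio.save_json(out / "rtop_report.json", report)
    _manifest_entry(cfg, "rtop", sorted(out.iterdir()))
    return report


def _stage_parcel_stats(cfg: PipelineConfig) -> dict:
    """Planted subdivision table -> ANOVA, post-hocs, stability."""
    out = Path(cfg.out_dir) / "parcel-stats"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("parcel-stats")
    summary = syn.make_parcel_table(cfg.n_subjects, seed=seed)
    summary.to_csv(out / "parcel_summary.csv", index=False)
    anova = sf.two_way_rm_anova(summary)
    posthoc = sf.posthoc_paired_ttests(summary)
    posthoc.to_csv(out / "posthoc.csv", index=False)
    sizes = [n for n in cfg.stability_sample_sizes if n <= cfg.n_subjects]
    stability = sf.stability_analysis(
        summary, sizes, cfg.stability_resamples,
        cfg.stability_alpha, cfg.stability_criterion, seed=seed,
    )
    stability.to_csv(out / "stability.csv", index=False)
    n = cfg.n_subjects
    report = {
        "anova": [dataclasses.asdict(a) for a in anova],
        "subdivision_df": [2, 2 * (n - 1)],
        "hemisphere_df": [1, n - 1],
        "ordering_detected": bool(
            (posthoc.loc[posthoc.contrast.str.contains("vAI vs dAI"), "sign"] < 0).all()
            and (posthoc.loc[posthoc.contrast.str.contains("dAI vs PI"), "sign"] < 0).all()
        ),
        "min_stable_n": {
            r.contrast: r.min_stable_n for r in stability.itertuples()
        },
    }
    rio.save_json(out / "parcel_report.json", report)
    _manifest_entry(cfg, "parcel-stats", sorted(out.iterdir()))
    return report


def _stage_gradients(cfg: PipelineConfig) -> dict:
    """Per-subject gradient fields -> group directional statistics."""
    out = Path(cfg.out_dir) / "gradients"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("gradients")
    planted = np.asarray(cfg.gradient_direction, dtype=float)
    planted /= np.linalg.norm(planted)

    rows = []
    directions: dict[tuple[str, str], list[np.ndarray]] = {}
    for s in range(cfg.n_gradient_subjects):
        ph = syn.make_surface_phantom(
            gradient_direction=planted, noise_sd=cfg.gradient_noise_sd,
            seed=seed + s,
        )
        for h in ("L", "R"):
            fld = gr.mesh_gradient(ph.meshes[h], ph.planted_field[h])
            for name in syn.SUBDIVISIONS:
                d = gr.main_direction(fld, ph.labels[h] == name)
                directions.setdefault((h, name), []).append(d)
                rows.append({"subject": s, "hemisphere": h, "subdivision": name,
                             "dx": d[0], "dy": d[1], "dz": d[2]})
    pd.DataFrame(rows).to_csv(out / "subject_directions.csv", index=False)

    tang = planted - np.array([0, 0, planted[2]])
    tang /= np.linalg.norm(tang)
    group = {}
    worst_err = 0.0
    for (h, name), ds in directions.items():
        st = gr.directional_stats(np.asarray(ds), seed=seed)
        err_deg = float(np.degrees(np.arccos(
            np.clip(st.mean_direction @ tang, -1, 1))))
        worst_err = max(worst_err, err_deg)
        group[f"{h}_{name}"] = {
            "mean_direction": st.mean_direction.tolist(),
            "mean_angle_rad": st.mean_angle,
            "dispersion_rad": st.dispersion,
            "sem_rad": st.sem,
            "ci_halfwidth_rad": st.ci_halfwidth,
            "rayleigh_statistic": st.rayleigh_statistic,
            "rayleigh_df": st.rayleigh_df,
            "rayleigh_p": st.rayleigh_p,
            "direction_error_deg": err_deg,
        }
    rio.save_json(out / "directional_stats.json", group)

    # isocontours of one subject's field on the left sheet
    ph = syn.make_surface_phantom(gradient_direction=planted,
                                  noise_sd=0.0, seed=seed)
    fvals = ph.planted_field["L"]
    levels = list(np.quantile(fvals, [0.25, 0.5, 0.75]))
    contours = gr.isocontours(ph.meshes["L"], fvals, levels)
    seg_rows = [
        {"level": lv, "x1": s0[0][0], "y1": s0[0][1], "z1": s0[0][2],
         "x2": s0[1][0], "y2": s0[1][1], "z2": s0[1][2]}
        for lv, segs in contours.items() for s0 in segs
    ]
    pd.DataFrame(seg_rows).to_csv(out / "isocontours.csv", index=False)

    report = {
        "max_direction_error_deg": worst_err,
        "max_rayleigh_p": max(g["rayleigh_p"] for g in group.values()),
        "n_subjects": cfg.n_gradient_subjects,
    }
    rio.save_json(out / "gradient_report.json", report)
    _manifest_entry(cfg, "gradients", sorted(out.iterdir()))
    return report


def _stage_connectivity(cfg: PipelineConfig) -> dict:
    """Seed connectivity on rest phantoms -> differential target masks."""
    out = Path(cfg.out_dir) / "connectivity"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("connectivity")
    betas: dict[str, list[np.ndarray]] = {}
    planted: dict[str, np.ndarray] = {}
    screened = 0
    for s in range(cfg.n_rest_subjects):
        ph = syn.make_rest_phantom(cfg.rest_grid, cfg.rest_timepoints,
                                   cfg.rest_tr, cfg.rest_coupling, seed=seed + s)
        if not conn.motion_screen(ph.motion_params).include:
            screened += 1
            continue
        clean = conn.preprocess_rest(ph.data, ph.tr)
        for key, sm in ph.seed_masks.items():
            beta = conn.seed_connectivity(clean, sm, ph.motion_params)
            betas.setdefault(key, []).append(beta)
        planted = ph.planted_targets
    target_mask = np.zeros(cfg.rest_grid, dtype=bool)
    for tm in planted.values():
        target_mask |= tm

    dices = {}
    masks_out = {}
    for h in ("L", "R"):
        seed_betas = {
            key: np.stack(betas[key]) for key in betas if key.startswith(h)
        }
        masks = conn.differential_subdivisions(seed_betas, target_mask,
                                               cfg.connectivity_alpha)
        for key, m in masks.items():
            dices[key] = conn.dice(m, planted[key])
            masks_out[key] = m
            rio.save_volume(out / f"mask_{key}.nii.gz",
                            m.astype(np.float32), np.eye(4))
    pairs = list(masks_out)
    disjoint = all(
        not np.any(masks_out[a] & masks_out[b])
        for i, a in enumerate(pairs) for b in pairs[i + 1:]
        if a[0] == b[0]
    )
    report = {
        "dice": dices,
        "min_dice": min(dices.values()),
        "masks_disjoint": bool(disjoint),
        "n_runs_excluded_by_motion": screened,
        "n_subjects": cfg.n_rest_subjects,
    }
    rio.save_json(out / "connectivity_report.json", report)
    _manifest_entry(cfg, "connectivity", sorted(out.iterdir()))
    return report


def _stage_cca(cfg: PipelineConfig) -> dict:
    """Brain-behavior phantom -> CCA, Pillai, LOO prediction."""
    out = Path(cfg.out_dir) / "cca"
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("cca")
    ph = syn.make_brain_behavior(cfg.n_cca_subjects, cfg.planted_canonical_r,
                                 cfg.missing_fraction, seed=seed)
    beh = pd.DataFrame(ph.behavior, columns=ph.behavior_columns).assign(
        subject=ph.subject_ids)
    br = pd.DataFrame(ph.brain, columns=ph.brain_columns).assign(
        subject=ph.subject_ids)
    beh_c, br_c, excl = bb.exclude_missing(beh, br)
    excl.to_csv(out / "exclusions.csv", index=False)
    X = br_c[list(ph.brain_columns)].to_numpy()
    Y = beh_c[list(ph.behavior_columns)].to_numpy()
    res = bb.fit_cca(X, Y)
    r1, p1 = bb.variate_correlation(res, axis=1)
    pred = bb.loo_predict(X, Y)
    pd.DataFrame({
        "subject": br_c["subject"], "predicted": pred.predicted,
        "actual": pred.actual,
    }).to_csv(out / "loo_scores.csv", index=False)
    report = {
        "n_retained": int(X.shape[0]),
        "n_excluded": int(len(excl)),
        "first_canonical_r": r1,
        "first_canonical_p": p1,
        "cohens_d_insample": bb.cohens_d_from_r(r1),
        "pillai_trace": res.pillai_trace,
        "pillai_p": res.pillai_p,
        "loo_prediction_r": pred.pearson_r,
        "loo_prediction_p": pred.p,
        "loo_cohens_d": pred.cohens_d,
        "planted_canonical_r": cfg.planted_canonical_r,
    }
    rio.save_json(out / "cca_report.json", report)
    _manifest_entry(cfg, "cca", sorted(out.iterdir()))
    return report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rtop": _stage_rtop,
    "parcel-stats": _stage_parcel_stats,
    "gradients": _stage_gradients,
    "connectivity": _stage_connectivity,
    "cca": _stage_cca,
}


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Execute one pipeline stage; returns its report dict."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    log.info("running stage %s (seed %d)", name, config.stage_seed(name))
    t0 = time.time()
    report = _STAGE_FUNCS[name](config)
    log.info("stage %s done in %.1f s", name, time.time() - t0)
    return report


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; emit a recovered-vs-planted synthesis report."""
    reports = {}
    for name in STAGES:
        try:
            reports[name] = run_stage(name, config)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    synthesis = {
        "rtop_max_relative_error": reports["rtop"]["max_relative_error"],
        "gradient_max_direction_error_deg":
            reports["gradients"]["max_direction_error_deg"],
        "connectivity_min_dice": reports["connectivity"]["min_dice"],
        "cca_recovery_error": abs(
            reports["cca"]["first_canonical_r"]
            - config.planted_canonical_r
        ),
        "stages": reports,
    }
    rio.save_json(Path(config.out_dir) / "report.json", synthesis)
    return synthesis
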