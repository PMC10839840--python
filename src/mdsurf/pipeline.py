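"""End-to-end pipeline orchestration.

A :class:`PipelineConfig` (loadable from YAML) drives the stages in
dependency order — simulate -> conjunction / preference -> borders /
null simulation -> fingerprint -> report — with one global seed split
deterministically per stage, a provenance record next to every output
bundle, and structured logging of each threshold actually applied.
Rerunning with an identical config and inputs reproduces label and count
outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .activation import (
    areal_conjunction,
    areal_mean,
    composite_rgb,
    network_compare,
    subject_conjunction_overlap,
    task_preference,
)
from .borders import (
    NullSimConfig,
    border_profile,
    border_proximity,
    homogeneous_null,
    top_fraction_overlap,
)
from .fingerprint import FingerprintConfig, fingerprint_cohort, winner_take_all
from .geometry import distance_segments, extract_borders
from .stats import MultipleComparisonConfig
from .synth import (
    default_ground_truth,
    homolog_area_pairs,
    make_mesh,
    make_parcellation,
    simulate_cohort,
    simulate_connectivity,
)

log = logging.getLogger("mdsurf.pipeline")

STAGES = ("simulate", "conjunction", "preference", "borders", "nullsim", "fingerprint")


@dataclass
class PipelineConfig:
    """All pipeline parameters and stage toggles."""

    out_dir: str = "mdsurf_out"
    seed: int = 0
    stages: tuple = STAGES
    # synthetic inputs
    mesh_kind: str = "icosphere"
    resolution: int = 2
    radius_mm: float = 32.0
    n_areas: int = 8
    n_subjects: int = 20
    # inference
    alpha: float = 0.05
    n_segments: int = 10
    top_fraction: float = 0.05
    overlap_threshold: float = 0.5
    fwhm_levels: tuple = (4.0, 12.0, 20.0)
    r_threshold: float = 0.2
    # optional externally supplied inputs (paths); simulate fills them in
    mesh_path: str | None = None
    labels_path: str | None = None
    cohort_dir: str | None = None
    connectivity_stem: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for tup in ("stages", "fwhm_levels"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage split of the global seed (below 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        """Hash of the computation-relevant parameters.

        Excludes ``out_dir`` and ``stages`` so that relocating outputs or
        toggling a stage leaves the other stages' outputs byte-identical.
        """
        d = asdict(self)
        d.pop("out_dir")
        d.pop("stages")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict = field(default_factory=dict)
    maps: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _write_provenance(cfg: PipelineConfig, out: Path, stage: str, extras: dict) -> None:
    rec = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seed": cfg.stage_seed(stage),
        **extras,
    }
    (out / f"provenance_{stage}.json").write_text(json.dumps(rec, indent=2, default=str))


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the requested stages in dependency order."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(out_dir=out)
    state: dict = {}

    if "simulate" in cfg.stages:
        _stage_simulate(cfg, out, state)
    else:
        _load_inputs(cfg, state)
    for stage in ("conjunction", "preference", "borders", "nullsim", "fingerprint"):
        if stage in cfg.stages:
            _require(state, stage)
            globals()[f"_stage_{stage}"](cfg, out, state, res)
    _stage_report(cfg, out, state, res)
    return res


def _require(state: dict, stage: str) -> None:
    needs = {
        "conjunction": ["mesh", "parc", "cohort"],
        "preference": ["mesh", "parc", "cohort"],
        "borders": ["mesh", "parc", "cohort", "borders"],
        "nullsim": ["mesh", "parc", "cohort", "borders"],
        "fingerprint": ["mesh", "parc", "cohort", "borders", "conn"],
    }[stage]
    missing = [k for k in needs if k not in state]
    if missing:
        raise RuntimeError(
            f"stage {stage!r} requires missing inputs {missing}: run the simulate "
            "stage or point the config at saved inputs"
        )


def _load_inputs(cfg: PipelineConfig, state: dict) -> None:
    if cfg.mesh_path:
        state["mesh"] = mio.load_surface_gifti(cfg.mesh_path)
    if cfg.labels_path:
        state["parc"] = mio.load_labels_gifti(cfg.labels_path)
    if "mesh" in state and "parc" in state:
        state["borders"] = extract_borders(state["mesh"], state["parc"])
    if cfg.cohort_dir:
        cohort = mio.load_cohort(cfg.cohort_dir)
        cohort.element_space = state.get("mesh")
        state["cohort"] = cohort
    if cfg.connectivity_stem:
        state["conn"] = mio.load_connectivity(cfg.connectivity_stem)


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> None:
    seed = cfg.stage_seed("simulate")
    mesh = make_mesh(cfg.mesh_kind, cfg.resolution, two_hemispheres=True,
                     seed=seed, radius=cfg.radius_mm)
    parc = make_parcellation(mesh, n_areas=cfg.n_areas, seed=seed)
    borders = extract_borders(mesh, parc)
    truth = default_ground_truth(mesh, parc, borders, seed=seed)
    cohort = simulate_cohort(mesh, parc, truth, n_subjects=cfg.n_subjects,
                             seed=seed, borders=borders)
    task_maps = truth.mean_field(mesh, parc, borders)
    conn = simulate_connectivity(mesh, parc, task_maps, truth, seed=seed,
                                 noise_rel=0.25)
    state.update(mesh=mesh, parc=parc, borders=borders, truth=truth,
                 cohort=cohort, conn=conn)
    sim = out / "inputs"
    sim.mkdir(exist_ok=True)
    mio.save_surface_gifti(mesh, sim / "mesh.surf.gii")
    mio.save_labels_gifti(parc, sim / "areas.label.gii")
    mio.save_cohort(cohort, sim / "cohort")
    mio.save_connectivity(conn, sim / "connectivity")
    truth_json = {
        "task_names": truth.task_names,
        "area_task_means": truth.area_task_means.tolist(),
        "gradient_spec": [list(map(str, g[:3])) + [g[3], g[4]] for g in truth.gradient_spec],
        "bump_spec": [[str(b[0]), b[1], b[2], b[3]] for b in truth.bump_spec],
        "seed_assignment": {str(k): v for k, v in truth.seed_assignment.items()},
        "noise_sd": truth.noise_sd,
        "noise_fwhm_mm": truth.noise_fwhm_mm,
        "subject_sd": truth.subject_sd,
    }
    (sim / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    _write_provenance(cfg, out, "simulate", {"n_vertices": mesh.n_vertices})
    log.info("simulate: %d vertices, %d areas, %d subjects",
             mesh.n_vertices, len(parc.areas), cohort.n_subjects)


def _stage_conjunction(cfg, out: Path, state: dict, res: PipelineResult) -> None:
    mesh, parc, cohort = state["mesh"], state["parc"], state["cohort"]
    areal = areal_mean(cohort, parc)
    areas = parc.areas
    mc = MultipleComparisonConfig(alpha=cfg.alpha, method="bonferroni",
                                  n_comparisons=len(areas))
    conj = areal_conjunction(areal, mc, areas=areas)
    conj_union = areal_conjunction(areal, mc, areas=areas,
                                   homolog_area_pairs=homolog_area_pairs(parc))
    log.info("conjunction: per-test alpha %.3e, %d areas survive",
             mc.effective_alpha, len(conj))
    overlap = subject_conjunction_overlap(cohort)
    mio.save_metric_gifti(overlap.counts.astype(float),
                          out / "subject_overlap.func.gii")
    import pandas as pd

    tbl = pd.DataFrame({"area": areas,
                        "conjunction": [a in conj for a in areas],
                        "conjunction_either_hemisphere": [a in conj_union for a in areas]})
    tbl.to_csv(out / "areal_conjunction.csv", index=False)
    res.tables["areal_conjunction"] = tbl
    res.maps["subject_overlap"] = overlap
    state["conjunction"] = conj
    _write_provenance(cfg, out, "conjunction",
                      {"effective_alpha": mc.effective_alpha,
                       "n_conjunction_areas": len(conj)})


def _stage_preference(cfg, out: Path, state: dict, res: PipelineResult) -> None:
    mesh, parc, cohort = state["mesh"], state["parc"], state["cohort"]
    pref = task_preference(cohort)
    core = parc.core_vertices()
    pref_core = task_preference(cohort, restrict=core) if core.size else None
    group = cohort.values.mean(axis=0)
    rgb = composite_rgb(group)
    nets = sorted({parc.area_network[a] for a in parc.areas} - {"other"})
    netcmp = network_compare(cohort, parc, nets, mesh=mesh, alpha=cfg.alpha)
    log.info("preference: labeled fraction %.3f (all), networks %s",
             pref.labeled_fraction(), nets)
    import pandas as pd

    pd.DataFrame({"v": np.arange(cohort.n_elements),
                  "label": pref.label}).to_csv(out / "task_preference.csv", index=False)
    mio.save_metric_csv(rgb.rgb.T.astype(float), out / "composite_rgb.csv",
                        names=["red", "green", "blue"])
    rows = []
    for net, entry in netcmp["networks"].items():
        for task, hem in entry["tasks"].items():
            for h, stats_ in hem.items():
                rows.append({"network": net, "task": task, "hemisphere": h, **stats_})
    pd.DataFrame(rows).to_csv(out / "network_means.csv", index=False)
    res.maps["preference"] = pref
    res.maps["preference_core"] = pref_core
    res.tables["network_compare"] = netcmp
    state["preference"] = pref
    _write_provenance(cfg, out, "preference",
                      {"labeled_fraction": pref.labeled_fraction()})


def _stage_borders(cfg, out: Path, state: dict, res: PipelineResult) -> None:
    mesh, parc, cohort = state["mesh"], state["parc"], state["cohort"]
    borders = state["borders"]
    core_pairs = [p for p in borders.adjacent_pairs
                  if any(parc.area_role[a] == "core" for a in p)]
    import pandas as pd

    rows = []
    profiles = {}
    for pair in core_pairs:
        try:
            seg = distance_segments(mesh, parc, borders, pair, cfg.n_segments)
        except ValueError:
            continue  # too few vertices for the requested segment count
        prof = border_profile(cohort, seg, pair, parc)
        profiles[pair] = prof
        inter = prof.interaction
        rows.append({"area_a": pair[0], "area_b": pair[1],
                     "F": inter["F"], "df_effect": inter["df_effect"],
                     "df_error": inter["df_error"], "p": inter["p_value"]})
    maps, surviving = top_fraction_overlap(cohort, cfg.top_fraction,
                                           cfg.overlap_threshold)
    prox = border_proximity(surviving, borders, mesh)
    log.info("borders: top fraction %.2f -> k=%d per map, %d survivors, "
             "proximity %.3f", cfg.top_fraction,
             int(np.ceil(cfg.top_fraction * cohort.n_elements)),
             surviving.size, prox)
    pd.DataFrame(rows).to_csv(out / "border_interactions.csv", index=False)
    pd.DataFrame({"metric": ["border_proximity"], "value": [prox]}).to_csv(
        out / "border_proximity.csv", index=False)
    res.tables["border_interactions"] = rows
    res.tables["border_proximity"] = prox
    state["profiles"] = profiles
    state["surviving"] = surviving
    _write_provenance(cfg, out, "borders",
                      {"n_surviving": int(surviving.size),
                       "border_proximity": prox})


def _stage_nullsim(cfg, out: Path, state: dict, res: PipelineResult) -> None:
    mesh, parc, cohort = state["mesh"], state["parc"], state["cohort"]
    borders = state["borders"]
    areal = areal_mean(cohort, parc)
    nullcfg = NullSimConfig(fwhm_levels=tuple(cfg.fwhm_levels),
                            n_subjects=cohort.n_subjects,
                            seed=cfg.stage_seed("nullsim"))
    nulls = homogeneous_null(areal, parc, mesh, nullcfg,
                             task_names=cohort.task_names)
    import pandas as pd

    rows = []
    for fwhm, null_cohort in nulls.items():
        _, surv = top_fraction_overlap(null_cohort, cfg.top_fraction,
                                       cfg.overlap_threshold)
        prox = border_proximity(surv, borders, mesh) if surv.size else np.nan
        rows.append({"fwhm_mm": fwhm, "n_surviving": int(surv.size),
                     "border_proximity": prox})
        log.info("nullsim: FWHM %.1f mm -> %d survivors, proximity %.3f",
                 fwhm, surv.size, prox)
    pd.DataFrame(rows).to_csv(out / "null_border_proximity.csv", index=False)
    res.tables["null_border_proximity"] = rows
    _write_provenance(cfg, out, "nullsim", {"fwhm_levels": list(cfg.fwhm_levels)})


def _stage_fingerprint(cfg, out: Path, state: dict, res: PipelineResult) -> None:
    mesh, parc, cohort = state["mesh"], state["parc"], state["cohort"]
    borders, conn = state["borders"], state["conn"]
    seeds = parc.core_vertices()
    fpcfg = FingerprintConfig(r_threshold=cfg.r_threshold, alpha=cfg.alpha)
    labels = fingerprint_cohort(conn, seeds, cohort.values, cohort.task_names,
                                parc, borders, mesh.homolog_map, fpcfg)
    counts, final = winner_take_all(labels, cohort.task_names)
    log.info("fingerprint: %d seeds, r threshold %.2f, %d labeled",
             seeds.size, fpcfg.r_threshold,
             int(np.sum(final != "none")))
    import pandas as pd

    tbl = pd.DataFrame({"seed": seeds, "final": final})
    for t, name in enumerate(cohort.task_names):
        tbl[f"count_{name}"] = counts[t]
    tbl.to_csv(out / "fingerprint_labels.csv", index=False)
    res.tables["fingerprint"] = tbl
    state["fingerprint_final"] = final
    _write_provenance(cfg, out, "fingerprint",
                      {"n_seeds": int(seeds.size),
                       "r_threshold": fpcfg.r_threshold})


def _stage_report(cfg, out: Path, state: dict, res: PipelineResult) -> None:
    lines = ["# mdsurf pipeline report", "",
             f"- config hash: `{cfg.config_hash()}`",
             f"- global seed: {cfg.seed}",
             f"- stages run: {', '.join(s for s in cfg.stages)}", ""]
    if "conjunction" in state:
        lines.append(f"- conjunction areas: {state['conjunction']}")
    if "preference" in state:
        lines.append(
            f"- preference labeled fraction: "
            f"{state['preference'].labeled_fraction():.3f}")
    if "surviving" in state:
        lines.append(f"- top-fraction survivors: {state['surviving'].size}")
    if "fingerprint_final" in state:
        n_lab = int(np.sum(state["fingerprint_final"] != "none"))
        lines.append(f"- winner-take-all labeled seeds: {n_lab}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
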