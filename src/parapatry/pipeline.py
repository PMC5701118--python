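"""End-to-end runs: simulate -> overlay -> exclusion test, and
simulate/load -> GPA -> displacement suite, with machine-readable reports.

A run is driven by a nested config (YAML on disk or a plain dict).  One
global seed fans out to per-stage seeds through a stated splitting rule —
``numpy.random.SeedSequence(seed).spawn(...)``, each child reduced modulo
2**31 — recorded in the report so any stage can be rerun in isolation.
Reports are JSON-serializable; a digest that excludes the timestamp lets
reruns be compared byte-for-byte.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .displacement import (
    bg_pca,
    displacement_bootstrap,
    pairwise_mean_tests,
    size_anova,
)
from .exclusion import ZoneCounts, release_summary, run_exclusion_test
from .grids import (
    ZoneBox,
    classify_localities,
    dedup_localities,
    potential_sympatry,
    read_ascii_grid,
    read_localities,
    sympatry_zone_counts,
    threshold_mtp,
)
from .shape import allometry_correct, gpa_align, load_landmark_sample
from .simulate import (
    GridSimConfig,
    MorphoSimConfig,
    gen_landmark_sample,
    gen_localities,
    gen_suitability_grids,
)

logger = logging.getLogger("parapatry")

__all__ = [
    "load_config",
    "stage_seeds",
    "run_exclusion_pipeline",
    "run_displacement_pipeline",
    "report_digest",
    "write_report",
]


def load_config(source: str | Path | Mapping) -> dict:
    """Load a run config from YAML (or pass a mapping through)."""
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def stage_seeds(seed: int, names: Sequence[str]) -> dict[str, int]:
    """Deterministic per-stage seeds from one global seed.

    Children of ``SeedSequence(seed)`` in the order of ``names``, reduced
    modulo 2**31 so they stay valid 32-bit seeds.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, children)}


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _zones_from_config(config: Mapping) -> list[ZoneBox]:
    return [ZoneBox(z["label"], z["lon_min"], z["lon_max"],
                    z["lat_min"], z["lat_max"])
            for z in config.get("zones", [])]


def _provenance(config: Mapping, seed: int, seeds: Mapping[str, int]) -> dict:
    return {
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "seed_split_rule": "SeedSequence(seed).spawn(n); child state % 2**31",
        "stage_seeds": dict(seeds),
        "config": _jsonable(config),
    }


def run_exclusion_pipeline(config: Mapping | str | Path) -> dict:
    """Overlay + modified-binomial exclusion test (+ release summary).

    Two input paths: ``counts`` supplies the zone counts directly (the
    printed worked example is then a first-class input); otherwise grids and
    localities are loaded (or simulated under ``simulate:``), thresholded by
    the minimum-training-presence rule, intersected, and counted against the
    contact-zone boxes.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0))
    seeds = stage_seeds(seed, ["localities_a", "localities_b"])
    report: dict[str, Any] = {
        "provenance": _provenance(config, seed, seeds),
        "warnings": [],
    }
    zones = _zones_from_config(config)
    if not zones and "counts" not in config:
        report["warnings"].append("no contact zones configured; no tests run")

    if "counts" in config:
        c = config["counts"]
        counts = ZoneCounts(int(c["a_away"]), int(c["b_away"]),
                            {label: (int(ab[0]), int(ab[1]))
                             for label, ab in c.get("zones", {}).items()})
    else:
        if "simulate" in config:
            sim = GridSimConfig(**{**config["simulate"], "seed": seed})
            grid_a, grid_b = gen_suitability_grids(sim)
            loc_a = gen_localities(grid_a, sim.n_localities_a, "species_a",
                                   seeds["localities_a"])
            loc_b = gen_localities(grid_b, sim.n_localities_b, "species_b",
                                   seeds["localities_b"])
            localities = pd.concat([loc_a, loc_b], ignore_index=True)
            species_a, species_b = "species_a", "species_b"
        else:
            grid_a = read_ascii_grid(config["grid_a"])
            grid_b = read_ascii_grid(config["grid_b"])
            localities = read_localities(config["localities"])
            species_a = config["species_a"]
            species_b = config["species_b"]
        localities = dedup_localities(localities)
        bin_a = threshold_mtp(
            grid_a, localities[localities["species"] == species_a])
        bin_b = threshold_mtp(
            grid_b, localities[localities["species"] == species_b])
        mask = potential_sympatry(bin_a, bin_b)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            classified = classify_localities(localities, mask, zones)
        report["warnings"] += [str(w.message) for w in caught]
        a_away, b_away, per_zone = sympatry_zone_counts(
            classified, species_a, species_b, [z.label for z in zones])
        counts = ZoneCounts(a_away, b_away, per_zone)
        report["overlay"] = {
            "threshold_a": bin_a.threshold,
            "threshold_b": bin_b.threshold,
            "n_suitable_a": bin_a.n_suitable(),
            "n_suitable_b": bin_b.n_suitable(),
            "n_potential_sympatry": mask.n_suitable(),
            "n_localities_in_sympatry": int(
                (classified["in_potential_sympatry"]
                 & classified["in_extent"]).sum()),
        }
        rel = release_summary(classified,
                              {species_a: grid_a, species_b: grid_b},
                              mask, zones)
        report["release"] = rel.to_dict()

    report["counts"] = _jsonable(counts)
    results = run_exclusion_test(counts)
    for r in results:
        logger.info("zone %s: p0=%.6f, method=%s", r.zone_label, r.p0,
                    r.method)
    report["binomial_tests"] = [_jsonable(r) for r in results]
    return report


def run_displacement_pipeline(config: Mapping | str | Path) -> dict:
    """GPA -> allometry -> BG-PCA -> distances -> displacement test.

    Landmarks come from TPS + metadata CSV (``tps``/``metadata`` keys) or
    from the simulator (``simulate:``).  The size ANOVA runs on centroid
    size always, and on skull length / body mass when present.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0))
    seeds = stage_seeds(seed, ["simulate", "permutation", "bootstrap"])
    report: dict[str, Any] = {
        "provenance": _provenance(config, seed, seeds),
        "warnings": [],
    }
    if "simulate" in config:
        sim = MorphoSimConfig(**{**config["simulate"],
                                 "seed": seeds["simulate"]})
        sample = gen_landmark_sample(sim)
    else:
        sample = load_landmark_sample(config["tps"], config["metadata"])

    aligned = gpa_align(sample)
    report["gpa"] = {
        "n_specimens": sample.n_specimens,
        "k_landmarks": sample.k_landmarks,
        "n_iter": aligned.n_iter,
        "final_change": aligned.final_change,
    }
    allom = allometry_correct(aligned)
    report["allometry"] = {
        "percent_predicted": allom.percent_predicted,
        "slope_norm": float(np.linalg.norm(allom.slope_vector)),
    }
    use_resid = bool(config.get("allometry_correction", True))
    shapes = allom.residuals if use_resid else aligned.shape_matrix()
    report["shape_matrix"] = (
        "allometry-residual" if use_resid else "raw-aligned")
    labels = sample.group_labels()

    pca = bg_pca(shapes, labels)
    report["bg_pca"] = {
        "percent_variance": _jsonable(pca.percent_variance),
        "n_axes": int(pca.axes.shape[0]),
    }

    n_perm = int(config.get("n_perm", 10_000))
    tests = pairwise_mean_tests(shapes, labels, n_perm=n_perm,
                                seed=seeds["permutation"])
    report["pairwise_distance_tests"] = [_jsonable(t) for t in tests]

    n_boot = int(config.get("n_boot", 1_000))
    disp = displacement_bootstrap(shapes, labels, n_boot=n_boot,
                                  seed=seeds["bootstrap"])
    report["displacement"] = _jsonable(disp)

    anovas = {"centroid_size": size_anova(
        aligned.centroid_sizes, labels, "centroid_size")}
    for name, vals in (("skull_length", sample.skull_length),
                       ("body_mass", sample.body_mass)):
        if vals is None or not np.isfinite(np.asarray(vals, float)).any():
            report["warnings"].append(
                f"size ANOVA for {name} skipped: no records")
            continue
        anovas[name] = size_anova(vals, labels, name)
    report["size_anova"] = {k: _jsonable(v) for k, v in anovas.items()}
    return report


def report_digest(report: Mapping) -> str:
    """SHA-256 over the canonical JSON of a report, timestamp excluded."""
    clean = copy.deepcopy(dict(report))
    clean.get("provenance", {}).pop("timestamp", None)
    payload = json.dumps(_jsonable(clean), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
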