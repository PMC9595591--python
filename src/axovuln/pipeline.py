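"""End-to-end orchestration: demo plate generation and staged analysis runs.

A run consumes a data directory containing ``images/`` (one multichannel
TIFF per well), ``manifest.csv`` (well -> population, dose, image path,
exclusion flag) and optionally ``traces/`` (per-population roGFP trace
CSVs), executes the enabled stages in order — census, trace
(morphometry), varicosities, redox, stats — and writes one CSV per stage
plus a JSON run record (config snapshot, per-stage counts and exclusion
tallies, version, wall time).  Outputs are pure functions of
(inputs, config, master seed).
"""

from __future__ import annotations

import dataclasses
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .core import ConfigError, ImageField, VULNERABLE_POPULATIONS
from . import census as census_mod
from . import morphometry as morpho_mod
from . import redox as redox_mod
from . import stats as stats_mod
from . import varicosity as vari_mod
from .synthetic import (
    FieldSpec,
    TraceSpec,
    generate_field,
    generate_trace,
    traces_from_csv,
    traces_to_csv,
    write_field_fixture,
)

ALL_STAGES = ("census", "trace", "varicosities", "redox", "stats")

#: Demo-plate study conditions.  Vulnerable populations are given longer
#: axonal domains, a higher Syt-1-positive fraction and steeper
#: dose-response curves, the direction of the planted class difference.
DEMO_POPULATIONS = ("SNc", "LC", "R", "DMV", "VTA", "XII", "STR")
DEMO_DOSES_UM = (0, 100, 150, 200)
_DEMO_SURVIVAL = {
    "vulnerable": {0: 1.0, 100: 0.70, 150: 0.45, 200: 0.30},
    "resilient": {0: 1.0, 100: 0.85, 150: 0.70, 200: 0.55},
}
_DEMO_NEURITE_UM = {"vulnerable": 950.0, "resilient": 550.0}
_DEMO_SYT1_POS = {"vulnerable": 0.75, "resilient": 0.35}
_DEMO_BASE_NEURONS = 10


@dataclass
class RunConfig:
    """Configuration of one pipeline run (single plate)."""

    data_dir: Path
    out_dir: Path
    pixel_size_um: float = 0.3
    stages: tuple[str, ...] = ALL_STAGES
    master_seed: int = 0
    min_soma_area_um2: float = census_mod.DEFAULT_MIN_SOMA_AREA_UM2
    strict_length_gate: bool = False
    n_resamples: int = stats_mod.DEFAULT_N_RESAMPLES
    control_population: str = "SNc"
    drift_limit: float = redox_mod.DEFAULT_DRIFT_LIMIT
    response_k: float = redox_mod.DEFAULT_RESPONSE_K

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.pixel_size_um <= 0 or self.n_resamples < 1:
            raise ConfigError("pixel_size_um and n_resamples must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        raw = {**raw.pop("run", {}), **raw}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["data_dir"] = str(self.data_dir)
        d["out_dir"] = str(self.out_dir)
        d["stages"] = list(self.stages)
        return d


@dataclass
class RunRecord:
    config: dict
    version: str = _version
    stage_seconds: dict[str, float] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _demo_class(pop: str) -> str:
    return "vulnerable" if pop in VULNERABLE_POPULATIONS else "resilient"


def make_demo_dataset(
    out_dir: str | Path,
    seed: int = 0,
    wells_per_dose: int = 3,
    rois_per_population: int = 12,
    field_px: int = 352,
) -> Path:
    """Generate a synthetic 7-population x 4-dose plate.

    Writes ``images/<well>.tif`` (+ truth sidecars), ``manifest.csv`` and
    per-population roGFP trace CSVs under ``traces/`` (with planted ~10%
    drifting and ~10% non-responding ROIs).
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for pop in DEMO_POPULATIONS:
        klass = _demo_class(pop)
        for dose in DEMO_DOSES_UM:
            frac = _DEMO_SURVIVAL[klass][dose]
            for w in range(wells_per_dose):
                well_id = f"{pop}_d{dose}_w{w}"
                n_neurons = max(
                    int(round(_DEMO_BASE_NEURONS * frac + rng.normal(0.0, 0.8))), 0
                )
                length = _DEMO_NEURITE_UM[klass] * frac * rng.normal(1.0, 0.08)
                spec = FieldSpec(
                    width_px=field_px,
                    height_px=field_px,
                    n_neurons=n_neurons,
                    neurite_total_length_um=max(length, 0.0),
                    syt1_pos_fraction=_DEMO_SYT1_POS[klass],
                    seed=int(rng.integers(0, 2**31)),
                )
                fld, truth = generate_field(spec)
                fld.field_id = well_id
                write_field_fixture(fld, truth, out_dir / "images", well_id)
                rows.append(
                    {
                        "well_id": well_id,
                        "population": pop,
                        "dose_um": dose,
                        "image": f"images/{well_id}.tif",
                        "excluded": False,
                    }
                )
        traces = []
        for r in range(rois_per_population):
            u = rng.random()
            drift = float(rng.uniform(0.15, 0.25)) * (1 if rng.random() < 0.5 else -1) \
                if u < 0.10 else float(rng.normal(0.0, 0.02))
            responder = not (0.10 <= u < 0.20)
            ox = float(rng.uniform(0.2, 0.8))
            f_dtt, f_ald = 200.0, 40.0
            f_base = f_ald + (1.0 - ox) * (f_dtt - f_ald)
            spec_t = TraceSpec(
                f_baseline=f_base, f_dtt=f_dtt, f_ald=f_ald,
                drift_fraction=drift, responder=responder,
                seed=int(rng.integers(0, 2**31)),
            )
            trace, _ = generate_trace(spec_t)
            trace.roi_id = f"{pop}_roi{r}"
            traces.append(trace)
        traces_to_csv(traces, out_dir / "traces" / f"{pop}.csv")
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def _load_manifest(config: RunConfig) -> pd.DataFrame:
    path = config.data_dir / "manifest.csv"
    if not path.exists():
        raise ConfigError(f"manifest not found: {path}")
    manifest = pd.read_csv(path)
    required = {"well_id", "population", "dose_um", "image"}
    missing = required - set(manifest.columns)
    if missing:
        raise ConfigError(f"manifest missing columns: {sorted(missing)}")
    if "excluded" not in manifest.columns:
        manifest["excluded"] = False
    for img in manifest["image"]:
        if not (config.data_dir / img).exists():
            raise ConfigError(f"image file missing: {config.data_dir / img}")
    return manifest


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute the enabled stages in order; any stage failure halts with a
    stage-tagged error."""
    manifest = _load_manifest(config)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=config.snapshot())
    state: dict[str, pd.DataFrame] = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGES[stage](config, manifest, state, record)
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
    record.to_json(config.out_dir / "run_record.json")
    return record


def _active_wells(manifest: pd.DataFrame) -> pd.DataFrame:
    return manifest[~manifest["excluded"].astype(bool)]


def _stage_census(config, manifest, state, record) -> None:
    rows = []
    for _, rec in _active_wells(manifest).iterrows():
        fld = ImageField.from_tiff(
            config.data_dir / rec["image"], pixel_size_um=config.pixel_size_um
        )
        mask = census_mod.segment_somata(
            fld, min_soma_area_um2=config.min_soma_area_um2
        )
        rows.append(
            {
                "well_id": rec["well_id"],
                "population": rec["population"],
                "dose_um": rec["dose_um"],
                "count": census_mod.count_neurons(mask),
            }
        )
    counts = pd.DataFrame(rows)
    survival = census_mod.normalize_survival(counts)
    counts.to_csv(config.out_dir / "counts.csv", index=False)
    survival.to_csv(config.out_dir / "survival.csv", index=False)
    state["counts"] = counts
    state["survival"] = survival
    record.stage_counts["census"] = {
        "wells": int(len(counts)),
        "excluded_wells": int(manifest["excluded"].astype(bool).sum()),
    }


def _dose0_wells(config, manifest) -> pd.DataFrame:
    active = _active_wells(manifest)
    return active[active["dose_um"] == 0]


def _stage_trace(config, manifest, state, record) -> None:
    rows = []
    skeletons = {}
    for _, rec in _dose0_wells(config, manifest).iterrows():
        fld = ImageField.from_tiff(
            config.data_dir / rec["image"], pixel_size_um=config.pixel_size_um
        )
        mask = census_mod.segment_somata(
            fld, min_soma_area_um2=config.min_soma_area_um2
        )
        graph, result = morpho_mod.measure_field(
            fld, mask, well_id=rec["well_id"], n_neurons=mask.count
        )
        skeletons[rec["well_id"]] = graph
        rows.append(
            {
                "well_id": rec["well_id"],
                "population": rec["population"],
                **{
                    k: getattr(result, k)
                    for k in (
                        "total_neurite_length_um", "n_segments", "n_neurons",
                        "mean_length_per_neuron_um", "segments_per_neuron",
                        "mean_segment_length_um", "valid",
                    )
                },
            }
        )
    morpho = pd.DataFrame(rows)
    morpho.to_csv(config.out_dir / "morphometry.csv", index=False)
    state["morphometry"] = morpho
    state["skeletons"] = skeletons
    record.stage_counts["trace"] = {
        "wells": int(len(morpho)),
        "excluded_no_neurons": int((~morpho["valid"]).sum()) if len(morpho) else 0,
    }


def _stage_varicosities(config, manifest, state, record) -> None:
    if "skeletons" not in state:
        _stage_trace(config, manifest, state, record)
    per_field = []
    per_vari = []
    detections_by_well: dict[str, list] = {}
    wells = list(_dose0_wells(config, manifest).iterrows())
    bg_mean = bg_sd = 0.0
    for _, rec in wells:
        well = rec["well_id"]
        fld = ImageField.from_tiff(
            config.data_dir / rec["image"], pixel_size_um=config.pixel_size_um
        )
        graph = state["skeletons"][well]
        detections_by_well[well] = vari_mod.detect_varicosities(
            fld, graph, strict_length_gate=config.strict_length_gate
        )
        syt1_img = fld.channel("syt1")
        bg_mean += float(np.median(syt1_img)) / max(len(wells), 1)
        bg_sd += float(np.std(syt1_img)) / max(len(wells), 1)
    # one Syt-1 cutoff per run: the excluded-candidate pool is an
    # experiment-level calibration, shared by every well of the plate
    excluded_all = [
        v for dets in detections_by_well.values() for v in dets
        if not v.passes_gate
    ]
    cutoff, fallback = (
        vari_mod.syt1_cutoff(
            excluded_all, background_mean=bg_mean, background_sd=bg_sd
        )
        if wells
        else (float("nan"), True)
    )
    for _, rec in wells:
        well = rec["well_id"]
        graph = state["skeletons"][well]
        detections = detections_by_well[well]
        frac = vari_mod.classify_syt1(detections, cutoff)
        metrics = vari_mod.summarize(detections, graph.total_length_um, well)
        per_field.append(
            {
                "well_id": well,
                "population": rec["population"],
                "n_detected": metrics.n_detected,
                "n_passing": metrics.n_passing,
                "syt1_positive_fraction": frac,
                "mean_nn_distance_um": metrics.mean_nn_distance_um,
                "density_per_mm": metrics.density_per_mm,
                "syt1_cutoff": cutoff,
                "cutoff_fallback": fallback,
                "gate": metrics.gate,
            }
        )
        for v in detections:
            per_vari.append(
                {
                    "well_id": well,
                    "x_um": v.centroid_um[0],
                    "y_um": v.centroid_um[1],
                    "width_um": v.width_um,
                    "length_um": v.length_um,
                    "mean_syt1_intensity": v.mean_syt1_intensity,
                    "passes_gate": v.passes_gate,
                    "is_syt1_positive": v.is_syt1_positive,
                    "gate": v.gate,
                }
            )
    metrics_df = pd.DataFrame(per_field)
    metrics_df.to_csv(config.out_dir / "varicosity_metrics.csv", index=False)
    pd.DataFrame(per_vari).to_csv(config.out_dir / "varicosities.csv", index=False)
    state["varicosity_metrics"] = metrics_df
    record.stage_counts["varicosities"] = {
        "wells": int(len(metrics_df)),
        "detected": int(metrics_df["n_detected"].sum()) if len(metrics_df) else 0,
        "passing": int(metrics_df["n_passing"].sum()) if len(metrics_df) else 0,
    }


def _stage_redox(config, manifest, state, record) -> None:
    trace_dir = config.data_dir / "traces"
    rows = []
    n_drift = n_nonresp = 0
    if trace_dir.exists():
        for csv in sorted(trace_dir.glob("*.csv")):
            pop = csv.stem
            for trace in traces_from_csv(csv):
                res = redox_mod.quantify_trace(
                    trace, config.drift_limit, config.response_k
                )
                n_drift += res.qc.excluded_drift
                n_nonresp += res.qc.excluded_nonresponder
                rows.append(
                    {
                        "population": pop,
                        "roi_id": res.roi_id,
                        "F": res.F,
                        "FDTT": res.FDTT,
                        "FALD": res.FALD,
                        "relative_oxidation": res.relative_oxidation,
                        "included": res.qc.included,
                        "excluded_drift": res.qc.excluded_drift,
                        "excluded_nonresponder": res.qc.excluded_nonresponder,
                        "drift_fraction": res.qc.drift_fraction,
                    }
                )
    oxidation = pd.DataFrame(rows)
    oxidation.to_csv(config.out_dir / "oxidation.csv", index=False)
    state["oxidation"] = oxidation
    record.stage_counts["redox"] = {
        "rois": int(len(oxidation)),
        "included": int(oxidation["included"].sum()) if len(oxidation) else 0,
        "excluded_drift": int(n_drift),
        "excluded_nonresponder": int(n_nonresp),
    }


def _stage_stats(config, manifest, state, record) -> None:
    comparisons = []
    seed = config.master_seed

    def add_estimates(results, measure):
        for r in results:
            comparisons.append(
                {
                    "measure": measure, "kind": "mean_difference_bca",
                    "group_a": r.group_a, "group_b": r.group_b,
                    "n_a": r.n_a, "n_b": r.n_b, "value": r.difference,
                    "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "p_raw": np.nan, "p_adjusted": np.nan, "adjustment": "",
                    "n_resamples": r.n_resamples, "seed": r.seed,
                }
            )

    def add_tests(results, measure):
        for t in results:
            comparisons.append(
                {
                    "measure": measure, "kind": t.name,
                    "group_a": t.groups[0] if len(t.groups) == 2 else "",
                    "group_b": t.groups[1] if len(t.groups) == 2 else "",
                    "n_a": np.nan, "n_b": np.nan, "value": t.statistic,
                    "ci_low": np.nan, "ci_high": np.nan,
                    "p_raw": t.p_raw, "p_adjusted": t.p_adjusted,
                    "adjustment": t.adjustment, "n_resamples": np.nan,
                    "seed": np.nan,
                }
            )

    survival = state.get("survival")
    if survival is not None and len(survival):
        for dose in sorted(survival["dose_um"].unique()):
            if dose == 0:
                continue
            sub = survival[(survival["dose_um"] == dose) & survival["normalization_defined"]]
            groups = {
                pop: g["normalized"].to_numpy()
                for pop, g in sub.groupby("population")
                if len(g) >= 3
            }
            measure = f"normalized_survival_{int(dose)}uM"
            if config.control_population in groups and len(groups) >= 2:
                add_estimates(
                    stats_mod.shared_control_design(
                        groups, config.control_population,
                        n_resamples=config.n_resamples, master_seed=seed,
                    ),
                    measure,
                )
                add_tests(stats_mod.omnibus_and_posthoc(groups), measure)

    for state_key, column, measure in (
        ("morphometry", "mean_length_per_neuron_um", "mean_neurite_length"),
        ("morphometry", "segments_per_neuron", "segments_per_neuron"),
        ("varicosity_metrics", "syt1_positive_fraction", "syt1_positive_fraction"),
    ):
        table = state.get(state_key)
        if table is None or not len(table):
            continue
        ok = table[np.isfinite(table[column])]
        try:
            test, est = stats_mod.class_comparison(
                ok[column].to_numpy(), ok["population"].tolist(),
                n_resamples=config.n_resamples, seed=seed,
            )
        except ValueError:
            continue
        add_tests([test], measure)
        add_estimates([est], measure)

    stats_df = pd.DataFrame(comparisons)
    stats_df.to_csv(config.out_dir / "stats.csv", index=False)
    state["stats"] = stats_df
    record.stage_counts["stats"] = {"comparisons": int(len(stats_df))}


_STAGES = {
    "census": _stage_census,
    "trace": _stage_trace,
    "varicosities": _stage_varicosities,
    "redox": _stage_redox,
    "stats": _stage_stats,
}
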