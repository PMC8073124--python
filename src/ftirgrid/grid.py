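"""Preprocessing-grid enumeration, execution, and summary statistics.

A combination is one (denoise, baseline correction, normalization) method
triple with bound parameters.  The default grid expands to 2835
combinations: 45 denoise variants (Eilers λ ∈ {2..24}, Savitzky–Golay
{2,3} × odd frames 11..29, Fourier windows {100, 320}), 21 baseline
variants (second derivative {2,3} × odd frames 19..29, rubber band,
polynomial degrees 3..5, ALS λ ∈ {10⁶,10⁷,10⁸}, RMie-EMSC, ME-EMSC), and
3 normalizations (CON, TSN, PQN).  Each combination is applied
independently to the Kennard–Stone model and test sets and evaluated on
both tasks: PLSR against the ordinal progression coding and PLS-DA
against the class-membership matrix.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baseline as bl
from . import chemometrics as chem
from . import denoise as dn
from . import normalize as nm
from .core import (
    CO2_REGION,
    WATER_VAPOR_REGION,
    NoiseConfig,
    SpectralRegion,
    SpectraSet,
    add_scan_noise,
    interpolate_region,
    max_normalize_dataset,
    remove_region,
    trim_region,
)

logger = logging.getLogger(__name__)

STEPS = ("denoise", "baseline", "normalize")

_APPLY = {
    "denoise": dn.denoise_set,
    "baseline": bl.baseline_set,
    "normalize": nm.normalize_set,
}

_KNOWN_METHODS = {
    "denoise": {"EIL", "SG", "FT"},
    "baseline": {"DER", "RB", "POL", "ALS", "RMIE", "MEEMSC"},
    "normalize": {"CON", "TSN", "PQN"},
}


@dataclass(frozen=True)
class MethodSpec:
    """One preprocessing method with bound parameters."""

    step: str
    method: str
    params: tuple = ()  # sorted (name, value) pairs; hashable

    def __post_init__(self):
        if self.step not in STEPS:
            raise ValueError(f"unknown step {self.step!r}")
        if self.method.upper() not in _KNOWN_METHODS[self.step]:
            raise ValueError(f"unknown {self.step} method {self.method!r}")
        object.__setattr__(self, "method", self.method.upper())
        object.__setattr__(self, "params", tuple(sorted(dict(self.params).items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def label(self) -> str:
        if not self.params:
            return self.method
        inner = ",".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}" for k, v in self.params)
        return f"{self.method}({inner})"

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        return _APPLY[self.step](spectra, self.method, **self.param_dict)


@dataclass(frozen=True)
class GridConfig:
    """Expanded per-step method lists plus run options."""

    denoise: tuple
    baseline: tuple
    normalize: tuple
    noise: bool = True
    seed: int = 0
    lv_max: int = 8

    def __post_init__(self):
        for step in STEPS:
            specs = getattr(self, step)
            if not specs:
                raise ValueError(f"step {step!r} must list at least one method")
            if any(s.step != step for s in specs):
                raise ValueError(f"method spec bound to the wrong step under {step!r}")


def _expand(step: str, entries) -> tuple:
    """Expand [{method, grid:{param: [values]}}] into MethodSpecs (Cartesian
    product over each method's parameter grid, stable order)."""
    specs = []
    for entry in entries:
        method = entry["method"]
        grid = entry.get("grid", {})
        if not grid:
            specs.append(MethodSpec(step, method))
            continue
        names = list(grid)
        for combo in itertools.product(*(grid[n] for n in names)):
            specs.append(MethodSpec(step, method, tuple(zip(names, combo))))
    return tuple(specs)


def default_grid_config(noise: bool = True, seed: int = 0) -> GridConfig:
    """The study grid: 45 × 21 × 3 = 2835 combinations."""
    denoise = [
        {"method": "EIL", "grid": {"lambda": list(range(2, 25))}},
        {"method": "SG", "grid": {"poly_degree": [2, 3], "frame": list(range(11, 30, 2))}},
        {"method": "FT", "grid": {"window": [100, 320]}},
    ]
    baseline = [
        {"method": "DER", "grid": {"poly_degree": [2, 3], "frame": list(range(19, 30, 2))}},
        {"method": "RB"},
        {"method": "POL", "grid": {"degree": [3, 4, 5]}},
        {"method": "ALS", "grid": {"lambda": [1e6, 1e7, 1e8]}},
        {"method": "RMIE"},
        {"method": "MEEMSC"},
    ]
    normalize = [{"method": "CON"}, {"method": "TSN"}, {"method": "PQN"}]
    return GridConfig(
        _expand("denoise", denoise),
        _expand("baseline", baseline),
        _expand("normalize", normalize),
        noise=noise,
        seed=seed,
    )


def load_grid_config(path) -> GridConfig:
    """Read a YAML/JSON grid configuration (same schema as the defaults)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return GridConfig(
        _expand("denoise", raw["denoise"]),
        _expand("baseline", raw["baseline"]),
        _expand("normalize", raw["normalize"]),
        noise=raw.get("noise", True),
        seed=raw.get("seed", 0),
        lv_max=raw.get("lv_max", 8),
    )


def enumerate_combinations(cfg: GridConfig) -> list[tuple]:
    """Cartesian product of the per-step expansions, in stable
    denoise-major order; length = product of per-step totals."""
    return list(itertools.product(cfg.denoise, cfg.baseline, cfg.normalize))


# ---------------------------------------------------------------------------
# Pipeline execution


def preprocess_set(
    spectra: SpectraSet,
    triple,
    co2: SpectralRegion = SpectralRegion(*CO2_REGION),
    water: SpectralRegion = SpectralRegion(*WATER_VAPOR_REGION),
) -> SpectraSet:
    """Full single-set pipeline: drop the water-vapor region, denoise,
    interpolate across CO₂ (some baseline methods need a gap-free axis),
    correct the baseline, trim CO₂ out again, normalize."""
    d_spec, b_spec, n_spec = triple
    s = remove_region(spectra, water)
    s = d_spec.apply(s)
    s = interpolate_region(s, co2)
    s = b_spec.apply(s)
    s = trim_region(s, co2)
    return n_spec.apply(s)


@dataclass
class EvalRecord:
    """One combination × task outcome."""

    combination: str
    denoise: str
    baseline: str
    normalize: str
    task: str
    noise: bool = False
    chosen_lv: int = 0
    internal: float = np.nan
    external: float = np.nan
    failed: bool = False
    stage: str = ""
    message: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def run_combination(model_set: SpectraSet, test_set: SpectraSet, triple, task: str, lv_max: int = 8) -> EvalRecord:
    """Preprocess model and test sets independently with one method triple
    and evaluate one task.  Failures are captured in the record, never
    raised, so a grid sweep survives pathological combinations."""
    d_spec, b_spec, n_spec = triple
    rec = EvalRecord(
        combination="|".join(s.label() for s in triple),
        denoise=d_spec.label(),
        baseline=b_spec.label(),
        normalize=n_spec.label(),
        task=task,
    )
    try:
        stage = "preprocess"
        model_p = preprocess_set(model_set, triple)
        test_p = preprocess_set(test_set, triple)
        stage = task
        x_model, x_test = model_p.absorbance, test_p.absorbance
        if task == "regression":
            y_model = chem.regression_target(model_p.labels)
            y_test = chem.regression_target(test_p.labels)
            curve = chem.loocv_curve_regression(x_model, y_model, lv_max)
            lv = chem.select_lv_regression(curve)
            model = chem.pls_fit(x_model, y_model, lv)
            rec.internal = float(curve[lv - 1])
            rec.external = chem.rmsep(y_test, chem.pls_predict(model, x_test))
        elif task == "classification":
            order = chem._class_order_of(model_p.labels)
            curve = chem.loocv_curve_classification(x_model, model_p.labels, lv_max, order)
            lv = chem.select_lv_classification(curve)
            model = chem.pls_fit(x_model, chem.membership_matrix(model_p.labels, order), lv)
            pred = chem.plsda_assign(chem.pls_predict(model, x_test), order)
            rec.internal = float(curve[lv - 1])
            rec.external = chem.accuracy(test_p.labels, pred)
        else:
            raise ValueError(f"unknown task {task!r}")
        rec.chosen_lv = lv
    except Exception as exc:  # noqa: BLE001 — grid must keep going
        rec.failed = True
        rec.stage = stage
        rec.message = str(exc)
        logger.warning("combination %s failed at %s: %s", rec.combination, stage, exc)
    return rec


def run_grid(
    spectra: SpectraSet,
    cfg: GridConfig,
    tasks=("regression", "classification"),
    cache_dir=None,
    noise_cfg: NoiseConfig | None = None,
) -> pd.DataFrame:
    """Run every combination × task on clean data (and, when ``cfg.noise``,
    on a 32-scan noise-added copy).  The Kennard–Stone split is computed
    once on the raw data and reused throughout; per-combination records
    are cached as JSON when ``cache_dir`` is given, making reruns cheap
    and bitwise-identical.
    """
    split = chem.kennard_stone_split(spectra)
    variants = [(False, spectra)]
    if cfg.noise:
        ncfg = noise_cfg or NoiseConfig(seed=cfg.seed)
        variants.append((True, add_scan_noise(spectra, ncfg)))

    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    records = []
    for noisy, full in variants:
        model_set = full.select_ids(split.model_ids)
        test_set = full.select_ids(split.test_ids)
        for idx, triple in enumerate(enumerate_combinations(cfg)):
            for task in tasks:
                key = f"{int(noisy)}-{idx:05d}-{task}"
                if cache and (cache / f"{key}.json").exists():
                    records.append(json.loads((cache / f"{key}.json").read_text()))
                    continue
                rec = run_combination(model_set, test_set, triple, task, cfg.lv_max)
                rec.noise = noisy
                records.append(rec.to_dict())
                if cache:
                    (cache / f"{key}.json").write_text(json.dumps(rec.to_dict()))
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Exploration and summaries


def pca_explore(variant_sets: list[SpectraSet], tags: list[dict] | None = None, n_components: int = 5):
    """PCA over max-normalized, stacked preprocessing variants.

    Each variant is normalized to its dataset maximum so variants share a
    scale, then the stack is mean-centered and decomposed.  Returns a
    tidy scores table (one row per spectrum per variant, tagged for
    method-colored plotting) and the explained-variance ratios.
    """
    from sklearn.decomposition import PCA

    lengths = {s.n_variables for s in variant_sets}
    if len(lengths) != 1:
        raise ValueError("all variants must share the axis length")
    blocks, rows = [], []
    for v, s in enumerate(variant_sets):
        normed = max_normalize_dataset(s)
        blocks.append(normed.absorbance)
        tag = (tags[v] if tags else {}) or {}
        for k in range(s.n_spectra):
            rows.append({"variant": v, "id": s.ids[k], "label": s.labels[k], **tag})
    stacked = np.vstack(blocks)
    n_components = min(n_components, *stacked.shape)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(stacked)
    table = pd.DataFrame(rows)
    for c in range(n_components):
        table[f"PC{c + 1}"] = scores[:, c]
    return table, pca.explained_variance_ratio_


def summarize_threshold_counts(records: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Count classification combinations whose internal AND external
    accuracies exceed the threshold, per baseline × normalization cell."""
    df = records[(records["task"] == "classification") & (~records["failed"])]
    ok = df[(df["internal"] > threshold) & (df["external"] > threshold)]
    base_methods = sorted(df["baseline"].str.split("(").str[0].unique())
    norm_methods = sorted(df["normalize"].unique())
    out = pd.DataFrame(0, index=base_methods, columns=norm_methods)
    for _, row in ok.iterrows():
        out.loc[row["baseline"].split("(")[0], row["normalize"]] += 1
    return out


def summarize_best_decile(records: pd.DataFrame) -> dict:
    """Select the combinations in the bottom decile of BOTH RMSECV and
    RMSEP (ties by summed rank, stable order) and histogram the method
    membership of the selection per preprocessing step."""
    df = records[(records["task"] == "regression") & (~records["failed"])].reset_index(drop=True)
    n = len(df)
    k = int(np.ceil(0.1 * n))
    rank_cv = df["internal"].rank(method="first")
    rank_p = df["external"].rank(method="first")
    selected = df[(rank_cv <= k) & (rank_p <= k)]
    if selected.empty:
        order = (rank_cv + rank_p).sort_values(kind="stable").index[:k]
        selected = df.loc[order]
    hist = {}
    for step in STEPS:
        col = selected[step].str.split("(").str[0]
        hist[step] = col.value_counts().to_dict()
    return {"selected": selected, "histogram": hist}


def summarize_mean_errors(records: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean ± std of RMSECV (internal) and RMSEP (external)
    over every regression combination containing that method."""
    df = records[(records["task"] == "regression") & (~records["failed"])]
    rows = []
    for step in STEPS:
        methods = df[step].str.split("(").str[0]
        for m in sorted(methods.unique()):
            sub = df[methods == m]
            rows.append(
                {
                    "step": step,
                    "method": m,
                    "n": len(sub),
                    "rmsecv_mean": sub["internal"].mean(),
                    "rmsecv_std": sub["internal"].std(ddof=0),
                    "rmsep_mean": sub["external"].mean(),
                    "rmsep_std": sub["external"].std(ddof=0),
                }
            )
    return pd.DataFrame(rows)
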