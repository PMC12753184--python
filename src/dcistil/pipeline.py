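"""Batch orchestration: manifest -> scores -> validation report.

These functions are the library face of the command-line tool: they read a
tile manifest plus GeoJSON duct annotations, run the scoring pipeline per
patient, dichotomise at the cohort median (or a frozen threshold), and run
the cohort validation statistics against a per-patient outcome table.
Outputs are deterministic for a fixed config: rerunning produces
byte-identical CSVs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .cohort_stats import (
    InsufficientDataError,
    conditional_logistic,
    cox_fit,
    crosstab_summary,
    interaction_test,
    match_case_control,
)
from .config import ScoreConfig
from .exceptions import DcisTilError
from .microenvironment import AnnotationSet, rasterize_annotations
from .til_scoring import (
    TILScoreResult,
    analyze_tile,
    dichotomize,
    radius_sensitivity,
    score_from_analysis,
)
from .tissue_segmentation import CalibratedImage

SCORES_COLUMNS = ["patient_id", "n_patches", "stroma_mm2", "raw_density",
                  "score", "radius_um", "evaluable", "category", "threshold"]


def _load_tile(row: pd.Series, manifest_dir: Path) -> CalibratedImage:
    path = manifest_dir / str(row["path"])
    pixels = np.asarray(Image.open(path).convert("RGB"))
    return CalibratedImage(pixels=pixels, mpp=float(row["mpp"]))


def run_score(
    manifest_path: str | Path,
    annotations_dir: str | Path,
    config: ScoreConfig | None = None,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Score every tile in a manifest; one row per patient.

    Tiles with a missing or empty annotation are retained with
    ``evaluable=False`` and the run continues. A run log (config hash,
    package version, per-stage timings) is written next to the output CSV
    when ``out_path`` is given.
    """
    cfg = config or ScoreConfig()
    manifest_path = Path(manifest_path)
    annotations_dir = Path(annotations_dir)
    manifest = pd.read_csv(manifest_path)
    results: list[TILScoreResult] = []
    timings: dict[str, float] = {}
    for row in manifest.itertuples():
        row = pd.Series(row._asdict())
        tile_id = str(row["tile_id"])
        t0 = time.perf_counter()
        ann_path = annotations_dir / f"{tile_id}.geojson"
        try:
            image = _load_tile(row, manifest_path.parent)
            if not ann_path.exists():
                raise DcisTilError(f"missing annotation {ann_path.name}")
            ann = AnnotationSet.from_geojson(ann_path)
            dcis = rasterize_annotations(ann, image.shape, image.mpp)
            analysis = analyze_tile(image, dcis, cfg)
            results.append(score_from_analysis(analysis, tile_id, cfg))
        except DcisTilError:
            results.append(TILScoreResult(
                patient_id=tile_id, raw_density=None, score=None,
                radius_um=cfg.radius_um, n_patches=0, evaluable=False,
                score_mode=cfg.score_mode))
        timings[tile_id] = time.perf_counter() - t0

    threshold = cfg.threshold
    categories: dict[str, str] = {}
    evaluable = [r for r in results if r.evaluable]
    if len(evaluable) >= 2 or (threshold is not None and evaluable):
        assignments, threshold = dichotomize(results, threshold)
        categories = {a.patient_id: a.category for a in assignments}

    frame = pd.DataFrame([{
        "patient_id": r.patient_id,
        "n_patches": r.n_patches,
        "stroma_mm2": round(r.stroma_mm2, 6),
        "raw_density": None if r.raw_density is None else round(r.raw_density, 8),
        "score": None if r.score is None else round(r.score, 8),
        "radius_um": r.radius_um,
        "evaluable": r.evaluable,
        "category": categories.get(r.patient_id, ""),
        "threshold": "" if threshold is None else round(threshold, 8),
    } for r in results], columns=SCORES_COLUMNS)

    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_path, index=False)
        log = {"config_hash": cfg.config_hash(), "version": __version__,
               "n_tiles": len(frame),
               "n_evaluable": int(frame["evaluable"].sum()),
               "timings_s": {k: round(v, 4) for k, v in timings.items()}}
        out_path.with_suffix(".log.json").write_text(json.dumps(log, indent=2))
    return frame


def run_sensitivity(
    manifest_path: str | Path,
    annotations_dir: str | Path,
    radius_a_um: float = 250.0,
    radius_b_um: float = 200.0,
    config: ScoreConfig | None = None,
):
    """Radius-sensitivity analysis over a manifest of tiles."""
    cfg = config or ScoreConfig()
    manifest_path = Path(manifest_path)
    annotations_dir = Path(annotations_dir)
    manifest = pd.read_csv(manifest_path)
    analyses = []
    for row in manifest.itertuples():
        row = pd.Series(row._asdict())
        tile_id = str(row["tile_id"])
        ann_path = annotations_dir / f"{tile_id}.geojson"
        if not ann_path.exists():
            continue
        image = _load_tile(row, manifest_path.parent)
        ann = AnnotationSet.from_geojson(ann_path)
        dcis = rasterize_annotations(ann, image.shape, image.mpp)
        analyses.append((tile_id, analyze_tile(image, dcis, cfg)))
    return radius_sensitivity(analyses, radius_a_um, radius_b_um, cfg)


def _fmt_term(t) -> str:
    return f"{t.hr:.2f} [{t.ci_low:.2f}-{t.ci_high:.2f}]; p={t.p:.4g}"


def run_validate(
    scores: str | Path | pd.DataFrame,
    cohort: str | Path | pd.DataFrame,
    config: ScoreConfig | None = None,
    out_dir: str | Path | None = None,
    covariates: list[str] | None = None,
    matched: bool = False,
    seed: int = 0,
) -> dict:
    """Validation statistics joining scores onto a per-patient outcome table.

    Produces crosstabs by TIL category, univariate and multivariate Cox
    tables per outcome, the radiotherapy- and tamoxifen-interaction
    analyses, and (optionally) the matched nested case-control analysis.
    Returns a dict of result objects; when ``out_dir`` is given, also
    writes machine-readable CSVs plus a plain-text report.
    """
    cfg = config or ScoreConfig()
    scores_df = scores if isinstance(scores, pd.DataFrame) \
        else pd.read_csv(scores)
    cohort_df = cohort if isinstance(cohort, pd.DataFrame) \
        else pd.read_csv(cohort)

    score_cols = scores_df[["patient_id", "score", "category", "evaluable"]]
    merged = cohort_df.drop(columns=[c for c in ("score", "category")
                                     if c in cohort_df.columns]) \
        .merge(score_cols, on="patient_id", how="inner")
    unjoined = sorted(set(cohort_df["patient_id"])
                      - set(scores_df["patient_id"]))
    merged = merged[merged["evaluable"].astype(bool)]

    report: list[str] = []
    results: dict = {"n": len(merged), "unjoined_ids": unjoined}
    report.append(f"dcistil validation report (config {cfg.config_hash()}, "
                  f"version {__version__})")
    report.append(f"patients joined and evaluable: {len(merged)}; "
                  f"cohort ids without scores: {len(unjoined)}")

    crosstab_covs = [c for c in ("age", "tumour_size", "grade", "necrosis",
                                 "er", "her2") if c in merged.columns]
    results["crosstabs"] = {}
    for cov in crosstab_covs:
        try:
            ct = crosstab_summary(merged, cov)
        except (DcisTilError, ValueError):
            continue
        results["crosstabs"][cov] = ct
        report.append(f"\n[{cov}] ({ct.test}, p={ct.p:.4g}, n={ct.n})")
        report.append(ct.table.to_string())

    n_events = int((merged["event"] != "none").sum())
    if n_events < 2:
        report.append("\ninsufficient events: Cox analyses skipped")
        results["cox"] = None
    else:
        default_covs = [c for c in ("age", "her2", "excision", "tumour_size",
                                    "grade", "necrosis", "tamoxifen",
                                    "radiotherapy") if c in merged.columns]
        multi_covs = ["category"] + (covariates or default_covs)
        results["cox"] = {}
        for outcome in ("IBE", "I-IBE", "DCIS-IBE"):
            block = {}
            try:
                block["univariate"] = cox_fit(merged, outcome, ["category"])
                block["multivariate"] = cox_fit(merged, outcome, multi_covs)
            except (DcisTilError, ValueError) as err:
                report.append(f"\n{outcome}: model not fitted ({err})")
                continue
            results["cox"][outcome] = block
            uni, multi = block["univariate"], block["multivariate"]
            report.append(
                f"\n{outcome}: events={uni.n_events}; univariate TIL-high "
                f"HR {_fmt_term(uni.term('category_high'))}; multivariate "
                f"(n={multi.n}) {_fmt_term(multi.term('category_high'))}")
        results["interactions"] = {}
        for treatment in ("radiotherapy", "tamoxifen"):
            if treatment not in merged.columns:
                continue
            try:
                ir = interaction_test(merged, "IBE", "category", treatment)
            except (DcisTilError, ValueError) as err:
                report.append(f"\n{treatment} interaction not fitted ({err})")
                continue
            results["interactions"][treatment] = ir
            subs = "; ".join(f"{k}: {_fmt_term(v)}"
                             for k, v in ir.subgroup_hrs.items())
            report.append(f"\n{treatment} x TIL interaction "
                          f"p={ir.p_interaction:.4g}; subgroup HRs {subs}")
        if matched:
            try:
                sets = match_case_control(merged, seed=seed)
                mor = conditional_logistic(sets, exposure="category")
                results["matched"] = mor
                report.append(
                    f"\nmatched case-control ({sets.n_sets} sets): OR "
                    f"{mor.odds_ratio:.2f} [{mor.ci_low:.2f}-{mor.ci_high:.2f}]"
                    f"; p={mor.p:.4g}")
            except (DcisTilError, ValueError) as err:
                report.append(f"\nmatched analysis not run ({err})")

    text = "\n".join(report) + "\n"
    results["report"] = text
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.txt").write_text(text)
        rows = []
        for outcome, block in (results.get("cox") or {}).items():
            for kind, fit in block.items():
                for t in fit.terms:
                    rows.append({"outcome": outcome, "model": kind,
                                 "term": t.name, "hr": t.hr,
                                 "ci_low": t.ci_low, "ci_high": t.ci_high,
                                 "p": t.p, "n": fit.n,
                                 "n_events": fit.n_events})
        if rows:
            pd.DataFrame(rows).to_csv(out_dir / "cox_terms.csv", index=False)
    return results
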