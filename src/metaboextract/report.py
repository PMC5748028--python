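"""Full study report: canonical TSV tables, run manifest, optional figures.

TSVs are the canonical interface; figures are optional renderings.  With the
same plate and criteria the report is byte-identical across runs (the
manifest carries no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .ionization import (
    efficiency_summary,
    flag_interference,
    flags_table,
    ionization_efficiency,
    relative_matrix_effect,
)
from .metrics import cv_summary, cv_table, fold_change_table
from .panel import PlateDataset
from .quantify import class_yield
from .recommend import RecommendationCriteria, recommend, recommendations_table

__all__ = ["render_report", "CANONICAL_TABLES"]

#: The seven canonical study tables, in write order.
CANONICAL_TABLES = (
    "class_yield.tsv",
    "cv.tsv",
    "fold_change.tsv",
    "ionization_efficiency.tsv",
    "matrix_effect.tsv",
    "interference_flags.tsv",
    "recommendations.tsv",
)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def render_report(
    plate: PlateDataset,
    out_dir: str | Path,
    criteria: RecommendationCriteria | None = None,
    figures: bool = False,
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Compute all study tables and write them (plus a manifest) to ``out_dir``.

    Returns {table name: path}.  I/O failures surface with the offending path.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    criteria = criteria or RecommendationCriteria()

    yields = class_yield(plate)
    cvs = cv_table(plate)
    cvsum = cv_summary(cvs)
    fc = fold_change_table(plate)
    eff = ionization_efficiency(plate)
    effsum = efficiency_summary(eff)
    me = relative_matrix_effect(plate)
    flags = flags_table(flag_interference(plate))
    recs = recommendations_table(recommend(plate, criteria))

    tables = {
        "class_yield.tsv": yields,
        "cv.tsv": cvs,
        "fold_change.tsv": fc,
        "ionization_efficiency.tsv": eff,
        "matrix_effect.tsv": me,
        "interference_flags.tsv": flags,
        "recommendations.tsv": recs,
        "cv_summary.tsv": cvsum,
        "ionization_efficiency_summary.tsv": effsum,
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = out / name
        try:
            _write_tsv(df, path)
        except OSError as exc:
            raise OSError(f"failed to write {path}: {exc}") from exc
        paths[name] = path

    if figures:
        from . import plots

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        plots.save_default_figures(plate, figdir)

    manifest = {
        "package": "metaboextract",
        "version": __version__,
        "n_wells": int(len(plate.wells)),
        "n_metabolites": int(plate.panel.n_metabolites),
        "criteria": {
            "weights": criteria.weights,
            "cv_threshold_pct": criteria.cv_threshold_pct,
            "exclude_flagged": criteria.exclude_flagged,
        },
        "files": {
            name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in paths.items()
        },
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest.json"] = mpath
    return paths
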