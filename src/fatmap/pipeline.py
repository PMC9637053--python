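"""End-to-end cohort analysis: extraction, stratification, SPM, peaks.

The pipeline reads a cohort CSV plus per-subject image/mask files, builds
each subject's normalized fat-distribution curve per muscle, stratifies
the cohort by clinical rules (patient/control, CEP damage, Pfirrmann
grade > 3 vs <= 3, Modic changes, VAS > 6 vs <= 6), and runs, per muscle
and comparison, an unpaired t-test on overall mean FI% and a 1D SPM
comparison of the curves, alongside per-subject peak summaries and
deep-region peak prevalence.  The three muscles are analyzed
independently and never pooled.

Dataset layout (as produced by :func:`fatmap.synthetic.generate_cohort`):

    <data_dir>/cohort.csv
    <data_dir>/<subject_id>/fat_fraction.nii
    <data_dir>/<subject_id>/mask_<muscle>[_<side>].png|.nii
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    DEEP_CUT,
    N_NODES,
    SUPERFICIAL_CUT,
    NormalizedProfile,
    build_radial_profile,
    detect_peak,
    normalize_profile,
    overall_mean_fi,
    peak_prevalence,
    smooth_profile,
    write_peaks_csv,
    write_profiles_csv,
)
from .geometry import CenterOfRotation, DiscGeometry, locate_cor
from .io import MUSCLES, CohortTable, MuscleMask, read_slice_bundle
from .spm import spm_ttest2, unpaired_ttest

logger = logging.getLogger(__name__)

__all__ = [
    "StratificationRule",
    "DEFAULT_RULES",
    "stratify",
    "extract_cohort_profiles",
    "run_analysis",
    "load_config",
]


@dataclass(frozen=True)
class StratificationRule:
    """Split a cohort into two disjoint subgroups by one clinical variable.

    ``variable`` is one of ``group``, ``cep_damage``, ``pfirrmann``,
    ``modic``, ``vas``.  Thresholded variables use ``threshold`` with
    subgroup A strictly above it; boolean variables put A = present;
    ``group`` puts A = patient.  ``within`` optionally restricts the rule
    to one group (e.g. CEP damage within patients only).
    """

    name: str
    variable: str
    threshold: float | None = None
    within: str | None = None

    def __post_init__(self) -> None:
        if self.variable not in ("group", "cep_damage", "pfirrmann", "modic", "vas"):
            raise ValueError(f"unknown stratification variable {self.variable!r}")


#: The study's comparisons: patient vs control plus pathology/symptom splits.
DEFAULT_RULES = (
    StratificationRule("group", "group"),
    StratificationRule("cep", "cep_damage"),
    StratificationRule("pfirrmann_gt3", "pfirrmann", threshold=3),
    StratificationRule("modic", "modic"),
    StratificationRule("vas_gt6", "vas", threshold=6),
)


def stratify(cohort: CohortTable, rule: StratificationRule) -> tuple[list[str], list[str]]:
    """Subject-id lists (A, B) under the rule; missing values are dropped.

    Pfirrmann: A = grade > 3, B = grade <= 3.  VAS: A = > 6, B = <= 6
    (thresholds configurable via the rule).  Booleans: A = present.
    Group: A = patient, B = control.  An empty subgroup raises, naming
    the rule.
    """
    df = cohort.data
    if rule.within is not None:
        df = df[df["group"] == rule.within]
    if rule.variable not in df.columns:
        raise ValueError(f"rule {rule.name!r}: column {rule.variable!r} missing from cohort")
    col = df[rule.variable]
    usable = df[col.notna()]
    n_dropped = len(df) - len(usable)
    if n_dropped:
        logger.info("rule %s: dropped %d subjects with missing %s", rule.name, n_dropped, rule.variable)
    if rule.variable == "group":
        a = usable[usable["group"] == "patient"]
        b = usable[usable["group"] == "control"]
    elif rule.variable in ("cep_damage", "modic"):
        vals = usable[rule.variable].astype(bool)
        a, b = usable[vals], usable[~vals]
    else:
        thr = rule.threshold
        if thr is None:
            thr = 3 if rule.variable == "pfirrmann" else 6
        vals = pd.to_numeric(usable[rule.variable])
        a, b = usable[vals > thr], usable[vals <= thr]
    if a.empty or b.empty:
        raise ValueError(f"stratification rule {rule.name!r} produced an empty subgroup")
    return list(a["subject_id"]), list(b["subject_id"])


def _discover_masks(subject_dir: Path) -> list[tuple[Path, str, str]]:
    """Find mask files and parse muscle/side from the file name."""
    specs = []
    for path in sorted(subject_dir.glob("mask_*")):
        stem = path.name[len("mask_"):]
        for suffix in (".nii.gz", ".nii", ".png"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        else:
            continue
        side = "merged"
        for s in ("left", "right"):
            if stem.endswith("_" + s):
                side = s
                stem = stem[: -(len(s) + 1)]
        specs.append((path, stem, side))
    return specs


def _subject_image(subject_dir: Path) -> Path:
    for name in ("fat_fraction.nii", "fat_fraction.nii.gz", "fat_fraction.png"):
        p = subject_dir / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no fat-fraction image found in {subject_dir}")


def extract_cohort_profiles(
    data_dir: str | Path,
    cohort: CohortTable,
    n_nodes: int = N_NODES,
    side_policy: str = "average",
) -> tuple[dict[str, dict[str, NormalizedProfile]], pd.DataFrame]:
    """Per-subject normalized curves and overall mean FI% for every muscle.

    ``side_policy`` governs bilateral masks: ``average`` builds one curve
    per side and averages them node-wise; ``left``/``right`` use one side;
    ``merged`` pools pixels from all sides into a single mask.  Subjects
    with no usable mask for a muscle are dropped from that muscle only.

    Returns ``(profiles[subject_id][muscle], overall_df)`` where
    ``overall_df`` has columns subject_id, muscle, overall_mean_fi.
    """
    if side_policy not in ("average", "left", "right", "merged"):
        raise ValueError(f"unknown side policy {side_policy!r}")
    data_dir = Path(data_dir)
    profiles: dict[str, dict[str, NormalizedProfile]] = {}
    overall_rows = []
    for sid in cohort.subject_ids:
        row = cohort.row(sid)
        sdir = data_dir / sid
        try:
            fi, masks = read_slice_bundle(_subject_image(sdir), _discover_masks(sdir), row)
            disc = DiscGeometry(
                (float(row["posterior_row"]), float(row["posterior_col"])),
                (float(row["anterior_row"]), float(row["anterior_col"])),
            )
            cor = locate_cor(disc)
        except Exception as exc:
            raise RuntimeError(f"failed loading subject {sid!r}: {exc}") from exc
        profiles[sid] = {}
        by_muscle: dict[str, list[MuscleMask]] = {}
        for m in masks:
            by_muscle.setdefault(m.muscle, []).append(m)
        for muscle, mlist in by_muscle.items():
            usable = [m for m in mlist if m.usable]
            if side_policy == "left":
                usable = [m for m in usable if m.side in ("left", "merged")]
            elif side_policy == "right":
                usable = [m for m in usable if m.side in ("right", "merged")]
            if not usable:
                logger.warning("subject %s: no usable %s mask; dropped for this muscle", sid, muscle)
                continue
            try:
                if side_policy == "merged" and len(usable) > 1:
                    pooled = MuscleMask(
                        np.logical_or.reduce([m.mask for m in usable]), muscle=muscle, side="merged"
                    )
                    usable = [pooled]
                side_curves = []
                for m in usable:
                    rp = smooth_profile(build_radial_profile(fi, m, cor))
                    side_curves.append(normalize_profile(rp, n_nodes=n_nodes))
                mean_fi = np.mean([c.fi for c in side_curves], axis=0)
                profiles[sid][muscle] = NormalizedProfile(
                    nodes=side_curves[0].nodes,
                    fi=mean_fi,
                    muscle=muscle,
                    subject_id=sid,
                    side="merged" if len(side_curves) > 1 else usable[0].side,
                    smoothed=True,
                )
                union = MuscleMask(
                    np.logical_or.reduce([m.mask for m in usable]), muscle=muscle, side="merged"
                )
                overall_rows.append(
                    {
                        "subject_id": sid,
                        "muscle": muscle,
                        "overall_mean_fi": overall_mean_fi(fi, union),
                    }
                )
            except Exception as exc:
                raise RuntimeError(f"subject {sid!r}, muscle {muscle!r}: {exc}") from exc
    return profiles, pd.DataFrame(overall_rows)


_DEFAULT_CONFIG = {
    "n_nodes": N_NODES,
    "alpha": 0.05,
    "sided": "two",
    "deep_cut": DEEP_CUT,
    "superficial_cut": SUPERFICIAL_CUT,
    "side_policy": "average",
    "muscles": list(MUSCLES),
    "comparisons": [{"name": "group", "variable": "group"}],
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    """Read a YAML config and fill in defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def run_analysis(config: Mapping | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full fat-mapping analysis described by a config.

    Required config keys: ``data_dir`` (dataset layout above) and
    ``out_dir`` (unless given as an argument).  Writes profile, peak and
    overall-mean CSVs, one SPM JSON per comparison x muscle, per-group
    mean curves, and a run manifest.  Deterministic given inputs: a rerun
    with the same config produces byte-identical outputs.

    Returns a summary dict keyed by ``<comparison>/<muscle>``.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(config)
    out_dir = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(cfg["data_dir"])

    cohort = CohortTable.from_csv(data_dir / "cohort.csv")
    profiles, overall = extract_cohort_profiles(
        data_dir, cohort, n_nodes=int(cfg["n_nodes"]), side_policy=cfg["side_policy"]
    )
    flat = [p for per_subj in profiles.values() for p in per_subj.values()]
    write_profiles_csv(flat, out_dir / "profiles.csv")
    write_peaks_csv(
        flat,
        out_dir / "peaks.csv",
        deep_cut=float(cfg["deep_cut"]),
        superficial_cut=float(cfg["superficial_cut"]),
    )
    overall.to_csv(out_dir / "overall_mean.csv", index=False)

    summary: dict = {"comparisons": {}, "peak_prevalence": {}}
    for muscle in cfg["muscles"]:
        muscle_profiles = [p for p in flat if p.muscle == muscle]
        if muscle_profiles:
            summary["peak_prevalence"][muscle] = {
                region: peak_prevalence(
                    muscle_profiles,
                    muscle=muscle,
                    region=region,
                    deep_cut=float(cfg["deep_cut"]),
                    superficial_cut=float(cfg["superficial_cut"]),
                )
                for region in ("deep", "intermediate", "superficial")
            }

    for comp in cfg["comparisons"]:
        rule = StratificationRule(
            name=comp["name"],
            variable=comp["variable"],
            threshold=comp.get("threshold"),
            within=comp.get("within"),
        )
        ids_a, ids_b = stratify(cohort, rule)
        for muscle in cfg["muscles"]:
            label = f"{rule.name}/{muscle}"
            curves_a = [profiles[s][muscle] for s in ids_a if muscle in profiles.get(s, {})]
            curves_b = [profiles[s][muscle] for s in ids_b if muscle in profiles.get(s, {})]
            if len(curves_a) < 2 or len(curves_b) < 2:
                logger.warning("comparison %s: too few usable subjects; skipped", label)
                continue
            try:
                result = spm_ttest2(
                    curves_a, curves_b, alpha=float(cfg["alpha"]), sided=cfg["sided"], label=label
                )
            except Exception as exc:
                raise RuntimeError(f"SPM failed for comparison {label!r}: {exc}") from exc
            ov = overall[overall["muscle"] == muscle].set_index("subject_id")["overall_mean_fi"]
            va = ov.reindex([s for s in ids_a if s in ov.index]).dropna()
            vb = ov.reindex([s for s in ids_b if s in ov.index]).dropna()
            t_overall, p_overall = unpaired_ttest(va.to_numpy(), vb.to_numpy())
            doc = result.to_dict()
            doc["overall_mean"] = {
                "mean_a": float(va.mean()),
                "mean_b": float(vb.mean()),
                "difference": float(va.mean() - vb.mean()),
                "t": t_overall,
                "p": p_overall,
            }
            doc["group_mean_curve_a"] = np.mean([c.fi for c in curves_a], axis=0).tolist()
            doc["group_mean_curve_b"] = np.mean([c.fi for c in curves_b], axis=0).tolist()
            fname = f"spm_{rule.name}_{muscle}.json"
            with open(out_dir / fname, "w") as fh:
                json.dump(doc, fh, sort_keys=True, indent=1)
            summary["comparisons"][label] = {
                "n_clusters": len(result.clusters),
                "clusters": [(c.start_percent, c.end_percent, c.p_value) for c in result.clusters],
                "overall_mean_difference": doc["overall_mean"]["difference"],
                "overall_mean_p": p_overall,
            }

    manifest = {
        "package_version": __version__,
        "config_sha256": _config_hash(cfg),
        "seed": int(cfg.get("seed", 0)),
        "n_subjects": len(cohort),
        "n_profiles": len(flat),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return summary
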