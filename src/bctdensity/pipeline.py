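"""End-to-end pipeline: volumes -> segmentation -> quadrants -> features ->
cohort tables -> age-regression fits.

Driven by a :class:`PipelineConfig` (round-trippable through YAML). Per-
volume failures are quarantined with the error message and the pipeline
continues; every parameter actually used is echoed to the run log (no
silent defaults).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fileio
from .cohort import quadrant_share_table, summaries_to_frame, summarize_by_age
from .features import compose_features
from .quadrants import assign_quadrants, locate_nipple
from .regression import fit_age_model
from .segmentation import SegmentationParams, segment_all

log = logging.getLogger(__name__)

#: Default model family per feature (volume grows ~log(age), gland content
#: decays ~1/age).
DEFAULT_FAMILIES = {"btv": "log", "mgv": "inverse", "pbd": "inverse"}


@dataclass
class PipelineConfig:
    """Configuration of a full cohort run.

    ``manifest`` is a CSV with columns ``path, age, laterality`` (optional
    ``patient_id``); paths are resolved relative to the manifest location.
    """

    manifest: str
    out_dir: str
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    columns_run_right_to_left: bool = True
    mu_fat: float | None = None
    mu_gland: float | None = None
    fit_families: dict = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    records: pd.DataFrame
    quarantined: list[tuple[str, str]]
    out_dir: Path


def process_volume(volume, config: PipelineConfig):
    """Segment one volume and compute its composition features."""
    seg = segment_all(volume, config.segmentation)
    nipple = locate_nipple(seg.label_map)
    partition = assign_quadrants(
        seg.label_map,
        nipple,
        volume.laterality,
        config.columns_run_right_to_left,
    )
    comp = compose_features(
        volume, seg.label_map, partition, config.mu_fat, config.mu_gland
    )
    return seg, partition, comp


def _record_from_composition(comp, age, patient_id, laterality) -> dict:
    rec = {
        "patient_id": patient_id,
        "age": int(age),
        "laterality": laterality,
        "btv": comp.btv["whole"],
        "mgv": comp.mgv["whole"],
        "pbd": comp.pbd_hu["whole"],
        "pbd_vol": comp.pbd_volumetric["whole"],
    }
    for q in ("UOQ", "UIQ", "LOQ", "LIQ"):
        rec[f"btv_{q}"] = comp.btv[q]
        rec[f"mgv_{q}"] = comp.mgv[q]
        rec[f"pbd_{q}"] = comp.pbd_hu[q]
        rec[f"share_btv_{q}"] = comp.share_btv[q]
        rec[f"share_mgv_{q}"] = comp.share_mgv[q]
        rec[f"pbd_ratio_{q}"] = comp.pbd_ratio[q]
    return rec


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Process every manifest volume; aggregate cohort tables and fits."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline config: %s", config.to_dict())
    manifest = pd.read_csv(config.manifest)
    for col in ("path", "age", "laterality"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    base = Path(config.manifest).parent

    records = []
    quarantined: list[tuple[str, str]] = []
    for i, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        pid = row.get("patient_id", i)
        try:
            volume = fileio.read_volume(path, laterality=row["laterality"])
            seg, partition, comp = process_volume(volume, config)
            stem = path.name.split(".")[0]
            fileio.write_labels(seg.label_map, out / f"{stem}_labels.nii.gz")
            fileio.write_json(
                {
                    "nipple": list(partition.nipple),
                    "density_trace": seg.density_trace,
                    "mu_fat": seg.mu_fat,
                    "mu_gland": seg.mu_gland,
                    "warnings": seg.warnings,
                },
                out / f"{stem}_segmentation.json",
            )
            fileio.write_features_csv(comp.to_frame(), out / f"{stem}_features.csv")
            records.append(
                _record_from_composition(comp, row["age"], pid, row["laterality"])
            )
            log.info("processed %s (density trace length %d)", path, len(seg.density_trace))
        except Exception as exc:  # quarantine, keep going
            quarantined.append((str(path), str(exc)))
            log.error("quarantined %s: %s", path, exc)

    records_df = pd.DataFrame(records)
    if len(records_df):
        fileio.write_features_csv(records_df, out / "records.csv")
        summaries = summarize_by_age(records_df, columns=["btv", "mgv", "pbd"])
        fileio.write_features_csv(summaries_to_frame(summaries), out / "age_groups.csv")
        share_cols = [c for c in records_df.columns if c.startswith(("share_", "pbd_ratio_"))]
        if share_cols:
            fileio.write_features_csv(
                quadrant_share_table(records_df), out / "quadrant_shares.csv"
            )
        fits = {}
        for feature, family in config.fit_families.items():
            try:
                fit = fit_age_model(records_df["age"], records_df[feature], family)
                fits[feature] = dataclasses.asdict(fit)
            except ValueError as exc:
                fits[feature] = {"error": str(exc)}
        fileio.write_json(fits, out / "fits.json")
    if quarantined:
        fileio.write_json(
            [{"path": p, "error": e} for p, e in quarantined], out / "quarantine.json"
        )
    return PipelineResult(records=records_df, quarantined=quarantined, out_dir=out)
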