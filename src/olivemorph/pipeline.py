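"""End-to-end cohort pipelines: mesh traits, rendered-photo traits, concordance.

Glue used by the examples, the CLI and the validation experiments: run the
3D pipeline over every mesh of a synthetic cohort, render per-variety
scenes and run the 2D pipeline over them, and reshape both into the
long-format trait tables the statistics layer consumes.

Objects in a rendered scene are paired with sample ids by centroid column
(scenes lay samples out in a single row in id order); the generic
top-most/left-most numbering of ``label_objects`` is kept for standalone
photographs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import image_morphometrics as im2d
from . import mesh_morphometrics as m3d
from .synthetic import GermplasmCohort, render_scene, OBJECT_COLOR

#: traits shared by both measurement methods, used for concordance
COMMON_TRAITS = ["length", "width", "shadow_area", "appendage_length"]

_SEGMENT_THRESHOLDS = im2d.HSBThresholds(hue=(60.0, 120.0))


def run_cohort_3d(
    cohort: GermplasmCohort,
    resolution: float = 0.01,
    angle_threshold: float = 45.0,
) -> pd.DataFrame:
    """Extract 3D traits from every sample mesh; one wide row per sample."""
    rows = []
    for _, rec in cohort.table.iterrows():
        mesh = cohort.build_mesh(rec["sample_id"])
        tr = m3d.extract_mesh_traits(mesh, angle_threshold=angle_threshold, resolution=resolution)
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "variety": rec["variety"],
                "organ": rec["organ"],
                "length": tr.length,
                "width": tr.width,
                "height": tr.height,
                "shadow_area": tr.shadow_area,
                "volume": tr.volume,
                "total_area": tr.total_area,
                "up_skin_area": tr.up_skin_area,
                "down_skin_area": tr.down_skin_area,
                "cog_x": tr.center_of_gravity[0],
                "cog_y": tr.center_of_gravity[1],
                "cog_z": tr.center_of_gravity[2],
                "appendage_length": tr.appendage_length,
            }
        )
    return pd.DataFrame(rows)


def run_cohort_2d(
    cohort: GermplasmCohort,
    resolution: float = 0.01,
    min_area_px: int = 200,
) -> pd.DataFrame:
    """Render per-variety scenes, segment them, measure every object.

    Each (variety, organ) group becomes one photograph holding its
    replicates in a row, mirroring a photo-box frame of five fruits or ten
    endocarps.  Returns one wide row per sample.
    """
    rows = []
    for (variety, organ), grp in cohort.table.groupby(["variety", "organ"], sort=True):
        meshes = [cohort.build_mesh(sid) for sid in grp["sample_id"]]
        rgb, _ = render_scene(meshes, resolution=resolution)
        mask = im2d.segment_hsb(rgb, _SEGMENT_THRESHOLDS, scale=resolution)
        objects = im2d.label_objects(mask, min_area_px=min_area_px)
        if len(objects) != len(meshes):
            raise RuntimeError(
                f"scene {variety}/{organ}: segmented {len(objects)} objects "
                f"for {len(meshes)} samples"
            )
        objects = sorted(objects, key=lambda o: np.nonzero(o.pixels)[1].mean())
        for sid, obj in zip(grp["sample_id"], objects):
            tr = im2d.compute_object_traits(obj)
            rows.append(
                {
                    "sample_id": sid,
                    "variety": variety,
                    "organ": organ,
                    "length": tr.length,
                    "width": tr.width,
                    "shadow_area": tr.shadow_area,
                    "appendage_length": tr.appendage_length,
                }
            )
    return pd.DataFrame(rows)


def to_long(wide: pd.DataFrame, method: str, traits: list[str] | None = None) -> pd.DataFrame:
    """Wide per-sample traits -> long trait table for the statistics layer."""
    traits = traits or COMMON_TRAITS
    long = wide.melt(
        id_vars=["sample_id", "variety", "organ"],
        value_vars=[t for t in traits if t in wide.columns],
        var_name="trait",
        value_name="value",
    )
    long["method"] = method
    return long[["sample_id", "variety", "organ", "method", "trait", "value"]]
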