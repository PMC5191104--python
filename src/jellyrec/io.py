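"""File-format glue: images, RoI/feature tables, model JSON.

Colour inputs are converted to 8-bit grey with the ITU-R BT.601 luma.
RoI tables use 0-based row-major pixel-centre coordinates.  Model files
are JSON: GP models store serialized infix expressions, elastic-net models
their coefficient vector and centering, SVM models their kernel
parameters, feature subset and standardization constants.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import elasticnet as en
from . import gp as gp_mod
from .features import FEATURE_NAMES, FeatureVector
from .imaging import RoI

ROI_CSV_HEADER = [
    "image_id", "center_row", "center_col", "angle_rad",
    "axM", "axm", "area_px", "valid",
]


def read_grey_image(path: str | Path) -> np.ndarray:
    """Load PNG/JPEG/TIFF as an 8-bit greyscale array (BT.601 luma)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def write_grey_image(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)


def rois_to_frame(rois: list[RoI]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id,
            "center_row": r.obb_center[0],
            "center_col": r.obb_center[1],
            "angle_rad": r.obb_angle,
            "axM": r.axM,
            "axm": r.axm,
            "area_px": r.blob.area_px,
            "valid": r.valid,
        }
        for r in rois
    ]
    return pd.DataFrame(rows, columns=ROI_CSV_HEADER)


def features_to_frame(entries: list[tuple[str, int, FeatureVector]],
                      labels: list | None = None) -> pd.DataFrame:
    rows = []
    for k, (image_id, roi_id, fv) in enumerate(entries):
        row = {"image_id": image_id, "roi_id": roi_id, **fv.as_dict()}
        row["label"] = labels[k] if labels is not None else "NA"
        rows.append(row)
    return pd.DataFrame(rows, columns=["image_id", "roi_id", *FEATURE_NAMES, "label"])


# ----------------------------------------------------------------------
# model JSON
# ----------------------------------------------------------------------

def save_model(model, path: str | Path, extra: dict | None = None) -> None:
    path = Path(path)
    if isinstance(model, gp_mod.Ensemble):
        doc = {
            "kind": "gp_ensemble",
            "members": [gp_mod.serialize_expression(m.tree) for m in model.members],
            "relevant_features": sorted(model.relevant_features),
            "feature_names": list(model.feature_names),
        }
    elif isinstance(model, gp_mod.Individual):
        doc = {
            "kind": "gp_individual",
            "expression": gp_mod.serialize_expression(model.tree),
            "raw_fitness": model.raw_fitness,
            "feature_names": list(FEATURE_NAMES),
        }
    elif isinstance(model, en.ElasticNetModel):
        doc = {
            "kind": "elastic_net",
            "beta": model.beta.tolist(),
            "selected": model.selected.tolist(),
            "tau_opt": model.tau_opt,
            "mu_opt": model.mu_opt,
            "centering": model.centering.tolist(),
        }
    else:
        from . import svmrfe as svm_mod

        if isinstance(model, svm_mod.SvmModel):
            doc = {
                "kind": "svm",
                "kernel": model.kernel,
                "C": model.C,
                "gamma": model.gamma,
                "feature_subset": np.asarray(model.feature_subset).tolist(),
                "standardization": {
                    "mean": model.scaler.mean.tolist(),
                    "std": model.scaler.std.tolist(),
                },
                "accuracy": model.accuracy,
            }
        else:
            raise TypeError(f"cannot serialize model of type {type(model)!r}")
    if extra:
        doc.update(extra)
    path.write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    """Load a JSON model usable for prediction (GP or elastic-net)."""
    doc = json.loads(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "gp_ensemble":
        members = [
            gp_mod.Individual(gp_mod.parse_expression(e)) for e in doc["members"]
        ]
        return gp_mod.Ensemble(
            members,
            frozenset(doc["relevant_features"]),
            tuple(doc.get("feature_names", FEATURE_NAMES)),
        )
    if kind == "gp_individual":
        return gp_mod.Individual(
            gp_mod.parse_expression(doc["expression"]), doc.get("raw_fitness")
        )
    if kind == "elastic_net":
        return en.ElasticNetModel(
            beta=np.asarray(doc["beta"], float),
            selected=np.asarray(doc["selected"], int),
            tau_opt=doc["tau_opt"],
            mu_opt=doc["mu_opt"],
            centering=np.asarray(doc["centering"], float),
        )
    if kind == "svm":
        raise ValueError(
            "svm model files store parameters only and are not reloadable "
            "for prediction; retrain with train-svm"
        )
    raise ValueError(f"unknown model kind {kind!r}")


def predict_with(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, gp_mod.Ensemble):
        return model.classify_batch(X)
    if isinstance(model, gp_mod.Individual):
        return gp_mod.classify_batch(model.tree, X)
    return model.predict(X)
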