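"""Indication-confounding annotation and consolidated result tables.

Confounding by indication — the treated disease itself raising the
miscarriage risk — is annotated from a user-editable drug-to-category
map over a five-category controlled vocabulary.  A bundled example map
covers well-known drugs; it is illustrative, replaceable data, not a
licensed terminology extract.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .records import normalize_drug_name

INDICATION_CATEGORIES = frozenset(
    {
        "autoimmune",
        "reproductive_tract_infection",
        "metabolic",
        "thyroid",
        "progestogen_use",
    }
)


@dataclass(frozen=True)
class IndicationMap:
    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for drug, cats in self.mapping.items():
            unknown = set(cats) - INDICATION_CATEGORIES
            if unknown:
                raise ValueError(
                    f"unknown indication categories {sorted(unknown)} for drug {drug!r}"
                )


def load_indication_map(path=None) -> IndicationMap:
    """Load a drug->categories YAML map; None loads the bundled example."""
    if path is None:
        text = resources.files("pvkit").joinpath("data/indication_map.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    return IndicationMap(
        {normalize_drug_name(k): frozenset(v or ()) for k, v in raw.items()}
    )


def annotate_indication_confounding(
    drugs: Sequence[str], indication_map: IndicationMap
) -> pd.DataFrame:
    """Per-drug confounding flag with triggering categories.

    Drugs absent from the map are left unflagged with an "unmapped" note
    (absence of evidence, not evidence of absence).
    """
    rows = []
    for drug in drugs:
        norm = normalize_drug_name(drug)
        cats = indication_map.mapping.get(norm)
        rows.append(
            {
                "drug": norm,
                "confounded": bool(cats),
                "categories": ";".join(sorted(cats)) if cats else "",
                "note": "" if cats is not None else "unmapped",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------


def _keyed(frame: pd.DataFrame | None, prefix: str) -> pd.DataFrame | None:
    if frame is None or frame.empty or "drug" not in frame.columns:
        return None
    out = frame.copy()
    out["drug"] = out["drug"].map(normalize_drug_name)
    dup = out["drug"][out["drug"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate drug keys after normalization: {sorted(dup)}")
    out = out.rename(columns={c: f"{prefix}_{c}" for c in out.columns if c != "drug"})
    return out


def consolidate(
    signals: pd.DataFrame | None = None,
    subgroups: pd.DataFrame | None = None,
    tto: pd.DataFrame | None = None,
    model_metrics: dict | None = None,
    confounding: pd.DataFrame | None = None,
    config: dict | None = None,
    seed: int | None = None,
    stage_counts: dict | None = None,
) -> dict:
    """Merge any subset of stage outputs into one per-drug master table
    plus a JSON-serializable run manifest (config hash, seed, row counts)."""
    master: pd.DataFrame | None = None
    for frame, prefix in ((signals, "signal"), (tto, "tto"), (confounding, "conf")):
        keyed = _keyed(frame, prefix)
        if keyed is None:
            continue
        master = keyed if master is None else master.merge(keyed, on="drug", how="outer")
    if master is None:
        master = pd.DataFrame(columns=["drug"])

    config_blob = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": seed,
        "stage_counts": stage_counts or {},
        "n_drugs": int(len(master)),
        "stages_present": {
            "signals": signals is not None,
            "subgroups": subgroups is not None,
            "tto": tto is not None,
            "model": model_metrics is not None,
            "confounding": confounding is not None,
        },
        "model_metrics": model_metrics or {},
    }
    bundle = {"master": master.sort_values("drug").reset_index(drop=True), "manifest": manifest}
    if subgroups is not None:
        bundle["subgroups"] = subgroups
    return bundle


def write_bundle(bundle: dict, directory) -> dict[str, str]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    master_path = directory / "master.csv"
    bundle["master"].to_csv(master_path, index=False)
    paths["master"] = str(master_path)
    if "subgroups" in bundle:
        sub_path = directory / "subgroups.csv"
        bundle["subgroups"].to_csv(sub_path, index=False)
        paths["subgroups"] = str(sub_path)
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(bundle["manifest"], indent=2, sort_keys=True))
    paths["manifest"] = str(manifest_path)
    return paths


def load_bundle(directory) -> dict:
    directory = Path(directory)
    bundle = {
        "master": pd.read_csv(directory / "master.csv"),
        "manifest": json.loads((directory / "manifest.json").read_text()),
    }
    sub = directory / "subgroups.csv"
    if sub.exists():
        bundle["subgroups"] = pd.read_csv(sub)
    return bundle
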