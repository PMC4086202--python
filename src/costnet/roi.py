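"""Node registry: region-of-interest table handling.

Each node of the connectivity graph is a cortical or subcortical region of
interest (ROI), defined by an activation peak in ICBM 152 millimetre space.
The default registry ships with the package: 62 ROIs spanning medial and
lateral premotor cortex, prefrontal cortex, parietal and extrastriate visual
areas, cerebellum, and 10 subcortical regions (caudate, putamen, ventral
striatum, thalamus).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ("name", "x", "y", "z", "category", "subcortical")

# Community labels used by the synthetic generator's modular covariance.
DORSAL_MOTOR = "dorsal_motor"
PREFRONTAL = "prefrontal"
VENTRAL_VISUAL = "ventral_visual"
SUBCORTICAL = "subcortical"

# Longest-prefix match on ROI names; order matters (PreSMA before SMA, etc.).
_PREFIX_COMMUNITY = (
    ("PreSMA", DORSAL_MOTOR),
    ("SMA", DORSAL_MOTOR),
    ("PMd", DORSAL_MOTOR),
    ("M1", DORSAL_MOTOR),
    ("IPL", DORSAL_MOTOR),
    ("DLPFC", PREFRONTAL),
    ("VLPFC", PREFRONTAL),
    ("APFC", PREFRONTAL),
    ("InsPost", PREFRONTAL),
    ("INS", PREFRONTAL),
    ("SOG", VENTRAL_VISUAL),
    ("MOG", VENTRAL_VISUAL),
    ("LG", VENTRAL_VISUAL),
    ("FG", VENTRAL_VISUAL),
    ("LOA", VENTRAL_VISUAL),
    ("Cereb", VENTRAL_VISUAL),
    ("PutPost", SUBCORTICAL),
    ("Put", SUBCORTICAL),
    ("Thal", SUBCORTICAL),
    ("Caudate", SUBCORTICAL),
    ("VS", SUBCORTICAL),
)


def load_roi_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate an ROI table.

    Parameters
    ----------
    path
        TSV file with columns ``name, x, y, z, category, subcortical``.
        When omitted, the packaged 62-ROI registry is returned.

    Returns
    -------
    pandas.DataFrame
        One row per node, indexed 0..N-1, ``subcortical`` as bool.
    """
    if path is None:
        with resources.as_file(
            resources.files("costnet.data").joinpath("roi_table.tsv")
        ) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return validate_roi_table(table)


def validate_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")
    if table["name"].duplicated().any():
        dupes = table.loc[table["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate ROI names: {dupes}")
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    if not pd.notna(coords).all() or not (abs(coords) < float("inf")).all():
        raise ValueError("non-finite ROI coordinates")
    out = table.copy().reset_index(drop=True)
    out["subcortical"] = out["subcortical"].astype(bool)
    return out


def subcortical_names(table: pd.DataFrame) -> list[str]:
    """Names of the subcortical ROIs, in table order."""
    mask = table["subcortical"].astype(bool).to_numpy()
    return table.loc[mask, "name"].tolist()


def default_module_assignment(table: pd.DataFrame) -> dict[str, str]:
    """Map each ROI name to a functional community by name prefix.

    Communities: dorsal motor (SMA/pre-SMA/PMd/M1/IPL), prefrontal
    (DLPFC/VLPFC/APFC/insula), ventral visual (occipital/fusiform/
    cerebellum), and subcortical (striatum/thalamus).
    """
    assignment: dict[str, str] = {}
    for name in table["name"]:
        for prefix, community in _PREFIX_COMMUNITY:
            if name.startswith(prefix):
                assignment[name] = community
                break
        else:
            raise ValueError(f"no community prefix matches ROI {name!r}")
    return assignment
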