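"""River typology classification from site geology and catchment altitude.

Sites are classified by the dominant geological sediment along the river
(chalk, limestone, clay, hard rock or peat) pooled into three geology
classes — Calcareous (chalk or limestone), Siliceous (clay or hard rock)
and Organic (peat) — crossed with a mean-catchment-altitude band
(High: >= 200 m, boundary inclusive; Low: < 200 m), giving six typology
classes.  Sites with missing sediment data or a tied dominant sediment are
excluded rather than guessed.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .errors import ClassificationError

#: Sediment categories, in the order used by the site CSV dialect.
SEDIMENTS = ("chalk", "limestone", "clay", "hardrock", "peat")

#: Geology class of each sediment.
GEOLOGY_OF_SEDIMENT = {
    "chalk": "Calcareous",
    "limestone": "Calcareous",
    "clay": "Siliceous",
    "hardrock": "Siliceous",
    "peat": "Organic",
}

GEOLOGY_CLASSES = ("Calcareous", "Organic", "Siliceous")

#: The six typology classes, alphabetical (reference class for modelling is the
#: first one, Calcareous/High).
TYPOLOGY_CLASSES = (
    "Calcareous/High",
    "Calcareous/Low",
    "Organic/High",
    "Organic/Low",
    "Siliceous/High",
    "Siliceous/Low",
)

#: Sentinel typology for sites that cannot be classified.
EXCLUDED = "excluded"

#: Altitude (metres) at and above which a site counts as High.
HIGH_ALTITUDE_M = 200.0

#: Site CSV dialect columns.
SITE_COLUMNS = (
    "site_id",
    "prop_chalk",
    "prop_limestone",
    "prop_clay",
    "prop_hardrock",
    "prop_peat",
    "mean_catchment_altitude_m",
)


def dominant_geology(
    proportions: Mapping[str, float],
    *,
    pooled: bool = False,
    tol: float = 1e-9,
) -> str | None:
    """Geology class of the dominant sediment, or ``None`` if the site is excluded.

    Parameters
    ----------
    proportions
        Mapping from sediment name (see :data:`SEDIMENTS`) to its proportion in
        [0, 1].  Missing or NaN entries mark the site as excluded.
    pooled
        If True, dominance is evaluated over the three pooled geology classes
        (summing their constituent sediments) rather than per individual
        sediment.  Default is per-sediment strict dominance.
    tol
        Two proportions within ``tol`` of each other count as tied, which
        excludes the site ("multiple dominant geologies").

    Returns
    -------
    One of ``"Calcareous"``, ``"Siliceous"``, ``"Organic"``; or ``None`` when
    the data are missing or the maximum is not unique.
    """
    values = {}
    for sed in SEDIMENTS:
        v = proportions.get(sed)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        v = float(v)
        if v < -tol or v > 1 + tol:
            raise ClassificationError(
                f"sediment proportion {sed}={v} outside [0, 1]"
            )
        values[sed] = v
    if sum(values.values()) > 1 + 1e-6:
        raise ClassificationError(
            f"sediment proportions sum to {sum(values.values()):.6f} > 1"
        )

    if pooled:
        pooled_vals = {g: 0.0 for g in GEOLOGY_CLASSES}
        for sed, v in values.items():
            pooled_vals[GEOLOGY_OF_SEDIMENT[sed]] += v
        items = sorted(pooled_vals.items(), key=lambda kv: -kv[1])
        if items[0][1] - items[1][1] <= tol:
            return None
        return items[0][0]

    items = sorted(values.items(), key=lambda kv: -kv[1])
    if items[0][1] - items[1][1] <= tol:
        return None  # tied dominant sediments
    return GEOLOGY_OF_SEDIMENT[items[0][0]]


def classify(geology: str | None, altitude_m: float) -> str:
    """Combine a geology class and altitude into one of the six typology classes.

    Altitude exactly at 200 m is High (boundary inclusive).  Raises
    :class:`ClassificationError` for an excluded/unknown geology or a
    non-finite altitude.
    """
    if geology not in GEOLOGY_CLASSES:
        raise ClassificationError(f"cannot classify excluded geology {geology!r}")
    if altitude_m is None or not math.isfinite(float(altitude_m)):
        raise ClassificationError(f"altitude {altitude_m!r} is not finite")
    band = "High" if float(altitude_m) >= HIGH_ALTITUDE_M else "Low"
    return f"{geology}/{band}"


def classify_sites(sites: pd.DataFrame, *, pooled: bool = False) -> pd.DataFrame:
    """Classify every row of a site table.

    Expects the site CSV dialect columns (:data:`SITE_COLUMNS`).  Returns a copy
    with a ``typology`` column holding one of the six classes or
    :data:`EXCLUDED`.  Every site maps to exactly one value (partition).
    """
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ClassificationError(f"site table missing columns: {missing}")
    out = sites.copy()
    labels = []
    for _, row in out.iterrows():
        props = {sed: row[f"prop_{sed}"] for sed in SEDIMENTS}
        geo = dominant_geology(props, pooled=pooled)
        alt = row["mean_catchment_altitude_m"]
        if geo is None or alt is None or (isinstance(alt, float) and math.isnan(alt)):
            labels.append(EXCLUDED)
        else:
            labels.append(classify(geo, alt))
    out["typology"] = labels
    return out


def read_sites(path) -> pd.DataFrame:
    """Read a site CSV in the documented dialect."""
    df = pd.read_csv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ClassificationError(f"site CSV missing columns: {missing}")
    return df
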