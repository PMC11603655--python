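"""Cortical parcellation: the 12 canonical regions and their Allen CCF subdivisions.

The dorsal-cortex parcellation groups Allen Common Coordinate Framework
subdivision acronyms into six functional territories per hemisphere:
prefrontal (F), motor (M), somatosensory (S), auditory (Aud), retrosplenial
(RSP) and visual (V).  Region names carry an ``L_``/``R_`` hemisphere prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Subdivision acronyms per functional territory (Allen CCF naming).
SUBDIVISION_GROUPS: dict[str, tuple[str, ...]] = {
    "S": ("SSp-bfd", "SSp-ll", "SSp-m", "SSp-n", "SSp-tr", "SSp-ul", "SSp-un", "SSs"),
    "M": ("MOp", "MOs"),
    "V": ("VISal", "VISam", "VISl", "VISp", "VISpl", "VISpm", "VISa", "VISli", "VISpor", "VISrl"),
    "Aud": ("AUDd", "AUDp", "AUDpo", "AUDv", "TEa"),
    "RSP": ("RSPagl", "RSPd", "RSPv"),
    "F": ("ACAd", "FRP", "ORBm", "PL"),
}

BASE_REGIONS: tuple[str, ...] = ("F", "M", "S", "Aud", "RSP", "V")
HEMISPHERES: tuple[str, ...] = ("L", "R")

#: Canonical ordering of the 12 grouped regions (anterior to posterior, L before R).
REGIONS: tuple[str, ...] = tuple(f"{h}_{r}" for r in BASE_REGIONS for h in HEMISPHERES)

#: Number of subdivisions per hemisphere in the grouping table.
N_SUBDIVISIONS_PER_HEMISPHERE = sum(len(v) for v in SUBDIVISION_GROUPS.values())


def homotopic_pairs() -> list[tuple[int, int]]:
    """Index pairs (left, right) of homotopic regions in canonical order."""
    idx = {name: i for i, name in enumerate(REGIONS)}
    return [(idx[f"L_{r}"], idx[f"R_{r}"]) for r in BASE_REGIONS]


def grouping_table() -> pd.DataFrame:
    """Long-format mapping of subdivision acronym (per hemisphere) to grouped region."""
    rows = []
    for base, subs in SUBDIVISION_GROUPS.items():
        for hemi in HEMISPHERES:
            for acr in subs:
                rows.append({"acronym": f"{hemi}_{acr}", "hemisphere": hemi, "region": f"{hemi}_{base}"})
    return pd.DataFrame(rows)


@dataclass
class RegionAtlas:
    """Integer-label raster plus the subdivision and grouping tables.

    ``label_image`` uses 0 for pixels outside the brain; every nonzero label
    must appear in ``subdivisions`` (columns: label, acronym, hemisphere), and
    every subdivision acronym must map to exactly one grouped region through
    ``grouping`` (columns: acronym, hemisphere, region).
    """

    label_image: np.ndarray
    subdivisions: pd.DataFrame
    grouping: pd.DataFrame = field(default_factory=grouping_table)

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2 or not np.issubdtype(self.label_image.dtype, np.integer):
            raise ValueError("label_image must be a 2-D integer raster")
        known = set(self.subdivisions["label"])
        present = set(np.unique(self.label_image)) - {0}
        missing = present - known
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from subdivision table")
        mapped = self.grouping.groupby("acronym")["region"].nunique()
        if (mapped > 1).any():
            bad = mapped[mapped > 1].index.tolist()
            raise ValueError(f"subdivisions map to multiple regions: {bad}")

    @property
    def region_names(self) -> tuple[str, ...]:
        return REGIONS

    def subdivision_to_region(self) -> dict[str, str]:
        return dict(zip(self.grouping["acronym"], self.grouping["region"]))

    def labels_for_region(self, region: str) -> list[int]:
        acr = self.grouping.loc[self.grouping["region"] == region, "acronym"]
        tab = self.subdivisions.set_index("acronym")["label"]
        return [int(tab[a]) for a in acr if a in tab.index]

    def save(self, directory: str | Path) -> None:
        """Write label raster (CSV of ints) and the two tables (CSV)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "labels.csv", self.label_image, fmt="%d", delimiter=",")
        self.subdivisions.to_csv(d / "subdivisions.csv", index=False)
        self.grouping.to_csv(d / "grouping.csv", index=False)
        (d / "atlas.json").write_text(json.dumps({"shape": list(self.label_image.shape)}))

    @classmethod
    def load(cls, directory: str | Path) -> "RegionAtlas":
        d = Path(directory)
        img = np.loadtxt(d / "labels.csv", dtype=np.int64, delimiter=",")
        subs = pd.read_csv(d / "subdivisions.csv")
        grp = pd.read_csv(d / "grouping.csv")
        return cls(label_image=img, subdivisions=subs, grouping=grp)


def synthetic_atlas(shape: tuple[int, int] = (128, 128), border: int = 2) -> RegionAtlas:
    """Build a schematic dorsal-cortex atlas on a raster of the given shape.

    The left half of the frame holds left-hemisphere subdivisions, the right
    half the right hemisphere; each hemisphere is split into horizontal strips,
    one per subdivision, ordered so a region's subdivisions are contiguous.
    A ``border``-pixel frame of zeros marks out-of-brain pixels.  This is a
    synthetic stand-in for a registered Allen CCF projection.
    """
    h, w = shape
    img = np.zeros(shape, dtype=np.int64)
    acronyms = [f"{hemi}_{acr}" for hemi in HEMISPHERES for base in BASE_REGIONS for acr in SUBDIVISION_GROUPS[base]]
    n_sub = N_SUBDIVISIONS_PER_HEMISPHERE
    rows = []
    label = 1
    usable_h = h - 2 * border
    usable_w = w - 2 * border
    half_w = usable_w // 2
    bounds = np.linspace(0, usable_h, n_sub + 1).astype(int)
    for hemi_i, hemi in enumerate(HEMISPHERES):
        c0 = border + hemi_i * half_w
        c1 = c0 + half_w
        for k in range(n_sub):
            r0, r1 = border + bounds[k], border + bounds[k + 1]
            if r1 <= r0:
                raise ValueError("raster too small for one strip per subdivision")
            img[r0:r1, c0:c1] = label
            acr = acronyms[hemi_i * n_sub + k]
            rows.append({"label": label, "acronym": acr, "hemisphere": hemi})
            label += 1
    return RegionAtlas(label_image=img, subdivisions=pd.DataFrame(rows))
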