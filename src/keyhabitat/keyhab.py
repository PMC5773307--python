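"""Key-habitat delineation and IUCN A2 assessment.

Intersects the historic occurrence surface with current suitability to
delineate key habitats, computes the overlap index, Area of Occupancy
(AOO), its decline relative to the historically suitable area, the
protected fraction, and the IUCN A2 category.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .classify import CATEGORIES, CATEGORY_CODES, SuitabilityIndexSurface
from .grid import BinaryMask, GridLayer

#: A2 band lower edges (closed): decline >= edge maps to the category.
IUCN_A2_BANDS = (
    (80.0, "Critically Endangered"),
    (50.0, "Endangered"),
    (30.0, "Vulnerable"),
)
BELOW_THRESHOLD = "Below-threshold"

_SEVERITY = {BELOW_THRESHOLD: 0, "Vulnerable": 1, "Endangered": 2,
             "Critically Endangered": 3}


def round_half_up(x: float) -> int:
    """Reporting convention for percentages (so 22.64 -> 23, 95.28 -> 95)."""
    return int(math.floor(x + 0.5))


def overlap_index(psi: GridLayer,
                  index: SuitabilityIndexSurface | GridLayer) -> GridLayer:
    """Cellwise product of the occurrence surface and the suitability index;
    nodata where either input is nodata."""
    idx_layer = index.layer if isinstance(index, SuitabilityIndexSurface) else index
    psi.require_same_geometry(idx_layer)
    mask = psi.mask & idx_layer.mask
    out = np.full(psi.shape, psi.nodata)
    out[mask] = psi.values[mask] * idx_layer.values[mask]
    return GridLayer(out, psi.cell_size, psi.origin, psi.nodata)


def delineate_key(
    psi: GridLayer,
    categories: GridLayer,
    t_psi: float,
    included: set[str] = frozenset({"excellent"}),
) -> BinaryMask:
    """1 where occurrence probability exceeds the threshold AND the current
    category is in ``included`` ({'excellent'} or {'good', 'excellent'})."""
    if not included:
        raise ValueError("included category set must not be empty")
    bad = set(included) - {"good", "excellent"}
    if bad:
        raise ValueError(f"only optimal categories may delineate key "
                         f"habitat, got {sorted(bad)}")
    psi.require_same_geometry(categories)
    codes = [CATEGORY_CODES[c] for c in included]
    mask = psi.mask & categories.mask & (psi.values > t_psi) \
        & np.isin(categories.values, codes)
    return BinaryMask(mask.astype(np.uint8), psi.cell_size, psi.origin)


def decline_and_category(aoo_now: float, aoo_hist: float
                         ) -> tuple[float, str]:
    """Percent AOO decline and the IUCN A2 category it maps to.

    decline = (1 - aoo_now / aoo_hist) * 100, floored at 0 when the present
    area exceeds the historic one. Band edges are closed at the lower
    bound: >=80 Critically Endangered, >=50 Endangered, >=30 Vulnerable.
    """
    if aoo_hist <= 0:
        raise ValueError("historic AOO must be positive")
    decline = max(0.0, (1.0 - aoo_now / aoo_hist) * 100.0)
    for edge, cat in IUCN_A2_BANDS:
        if decline >= edge:
            return decline, cat
    return decline, BELOW_THRESHOLD


def protected_overlap(mask: BinaryMask,
                      protected: BinaryMask) -> tuple[float, float]:
    """Area (km²) of ``mask`` inside ``protected`` and its percentage of the
    mask's area (raw; round with :func:`round_half_up` for reporting)."""
    mask.require_same_geometry(protected)
    if mask.area_km2 == 0:
        raise ValueError("mask has zero area")
    inter = BinaryMask(mask.values & protected.values, mask.cell_size,
                       mask.origin)
    pct = 100.0 * inter.area_km2 / mask.area_km2
    return inter.area_km2, pct


def historic_mask(psi: GridLayer, t_psi: float) -> BinaryMask:
    """Cells with occurrence probability above the threshold."""
    ok = psi.mask & (psi.values > t_psi)
    return BinaryMask(ok.astype(np.uint8), psi.cell_size, psi.origin)


@dataclass
class KeyHabitatReport:
    t_psi: float
    historic_km2: float
    aoo_key_km2: float
    aoo_expanded_km2: float
    decline_pct: float
    decline_pct_rounded: int
    iucn_category: str
    decline_expanded_pct: float
    decline_expanded_pct_rounded: int
    iucn_category_expanded: str
    protected_km2: float | None = None
    protected_pct: float | None = None
    protected_pct_rounded: int | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_report(
    psi: GridLayer,
    categories: GridLayer,
    t_psi: float,
    protected: BinaryMask | None = None,
) -> tuple[KeyHabitatReport, BinaryMask, BinaryMask]:
    """Full assessment: key and expanded key masks, AOO areas, declines
    against the historic (psi > t) area, protected overlap, and IUCN A2
    categories under both key-habitat definitions."""
    key = delineate_key(psi, categories, t_psi, {"excellent"})
    expanded = delineate_key(psi, categories, t_psi, {"good", "excellent"})
    hist = historic_mask(psi, t_psi)
    decline, cat = decline_and_category(key.area_km2, hist.area_km2)
    decline_e, cat_e = decline_and_category(expanded.area_km2, hist.area_km2)
    prot_km2 = prot_pct = prot_round = None
    if protected is not None and hist.area_km2 > 0:
        prot_km2, prot_pct = protected_overlap(hist, protected)
        prot_round = round_half_up(prot_pct)
    report = KeyHabitatReport(
        t_psi=t_psi,
        historic_km2=hist.area_km2,
        aoo_key_km2=key.area_km2,
        aoo_expanded_km2=expanded.area_km2,
        decline_pct=decline,
        decline_pct_rounded=round_half_up(decline),
        iucn_category=cat,
        decline_expanded_pct=decline_e,
        decline_expanded_pct_rounded=round_half_up(decline_e),
        iucn_category_expanded=cat_e,
        protected_km2=prot_km2,
        protected_pct=prot_pct,
        protected_pct_rounded=prot_round,
    )
    return report, key, expanded


def severity(category: str) -> int:
    """Ordinal severity of an IUCN A2 category (for monotonicity checks)."""
    return _SEVERITY[category]
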