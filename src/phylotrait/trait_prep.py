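"""Species trait schema, filtering, the dimorphism statistic and binarization rules."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesRecord",
    "BinaryTrait",
    "EXCLUSION_FLAGS",
    "REPRO_CATEGORIES",
    "REALISED_CATEGORIES",
    "records_to_table",
    "filter_species",
    "compute_dimorphism",
    "volume_ratio_from_width_ratio",
    "log10_transform",
    "binarize_by_center",
    "binarize_at_two",
    "binarize_repro_potential",
]

EXCLUSION_FLAGS = ("supercolonial", "social_parasite", "clonal", "hybrid")
REPRO_CATEGORIES = (1, 2, 3, 4)
REALISED_CATEGORIES = ("sexual", "male_only", "none")


@dataclass
class SpeciesRecord:
    """One species' trait measurements and filter flags.

    Reproductive-potential categories: 1 = full capacity for male and female
    offspring, 2 = reduced capacity, 3 = male offspring only, 4 = sterile.
    """

    species_id: str
    repro_potential: int | None = None
    realised_repro: str | None = None
    confidence: str = "described"  # described | inferred
    colony_size: float | None = None
    queen_number: float | None = None
    mating_frequency: float | None = None
    queen_head_widths_mm: Sequence[float] = field(default_factory=tuple)
    worker_head_widths_mm: Sequence[float] = field(default_factory=tuple)
    excluded_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.repro_potential is not None and self.repro_potential not in REPRO_CATEGORIES:
            raise ValueError(f"{self.species_id}: repro_potential must be in 1..4")
        if self.realised_repro is not None and self.realised_repro not in REALISED_CATEGORIES:
            raise ValueError(f"{self.species_id}: bad realised_repro {self.realised_repro!r}")
        for name in ("colony_size", "queen_number", "mating_frequency"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{self.species_id}: {name} must be > 0")
        for name in ("queen_head_widths_mm", "worker_head_widths_mm"):
            if any(not w > 0 for w in getattr(self, name)):
                raise ValueError(f"{self.species_id}: head widths must be > 0")
        bad = set(self.excluded_flags) - set(EXCLUSION_FLAGS)
        if bad:
            raise ValueError(f"{self.species_id}: unknown flags {sorted(bad)}")
        self.excluded_flags = frozenset(self.excluded_flags)

    @property
    def dimorphism(self) -> float | None:
        if not self.queen_head_widths_mm or not self.worker_head_widths_mm:
            return None
        return compute_dimorphism(self.queen_head_widths_mm, self.worker_head_widths_mm)


def records_to_table(records: Iterable[SpeciesRecord]) -> pd.DataFrame:
    """Flatten records into a species-indexed DataFrame (one row per species)."""
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "repro_potential": r.repro_potential,
                "realised_repro": r.realised_repro,
                "confidence": r.confidence,
                "colony_size": r.colony_size,
                "queen_number": r.queen_number,
                "mating_frequency": r.mating_frequency,
                "dimorphism": r.dimorphism,
                "excluded_flags": ";".join(sorted(r.excluded_flags)),
            }
        )
    df = pd.DataFrame(rows).set_index("species_id")
    return df


def filter_species(
    table: pd.DataFrame,
    required_fields: Sequence[str] = (),
    include_flagged: Mapping[str, bool] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Drop flagged species and species missing required fields.

    ``include_flagged`` may whitelist flags (e.g. ``{"supercolonial": True}``)
    for robustness re-runs.  Returns the retained table and a per-reason count
    report.
    """
    include = dict.fromkeys(EXCLUSION_FLAGS, False)
    include.update(include_flagged or {})
    report = {f: 0 for f in EXCLUSION_FLAGS}
    report["missing"] = 0
    keep = []
    for sp, row in table.iterrows():
        raw = row.get("excluded_flags", "")
        raw = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw)
        flags = [f for f in raw.split(";") if f]
        active = [f for f in flags if not include.get(f, False)]
        if active:
            report[active[0]] = report.get(active[0], 0) + 1
            continue
        if any(pd.isna(row.get(f)) for f in required_fields):
            report["missing"] += 1
            continue
        keep.append(sp)
    if not keep:
        raise ValueError("no species survive filtering")
    return table.loc[keep], report


def compute_dimorphism(
    queen_widths_mm: Sequence[float], worker_widths_mm: Sequence[float]
) -> float:
    """Queen-worker size dimorphism: mean queen width / minimum worker width.

    A value of 1.0 means queens and workers are the same size.  The ratio is
    unit-free (scale both lists by any constant and it is unchanged).
    """
    q = np.asarray(queen_widths_mm, dtype=float)
    w = np.asarray(worker_widths_mm, dtype=float)
    if q.size == 0 or w.size == 0:
        raise ValueError("both queen and worker width lists must be nonempty")
    if np.any(q <= 0) or np.any(w <= 0):
        raise ValueError("head widths must be positive")
    return float(q.mean() / w.min())


def volume_ratio_from_width_ratio(width_ratio: float, sig_figs: int = 2) -> float:
    """Implied overall size (volume) ratio assuming size ∝ width³."""
    if width_ratio <= 0:
        raise ValueError("width ratio must be positive")
    v = width_ratio**3
    if sig_figs is None:
        return v
    exponent = math.floor(math.log10(abs(v)))
    return round(v, -exponent + sig_figs - 1)


def log10_transform(value) -> float:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("log10 requires positive values")
    out = np.log10(arr)
    return float(out) if out.ndim == 0 else out


@dataclass
class BinaryTrait:
    """A species -> {0,1} map plus binarization metadata."""

    values: dict
    dropped: frozenset
    statistic: str  # median | mean | fixed-two
    center: float | None
    buffer_fraction: float

    def __post_init__(self) -> None:
        overlap = set(self.values) & set(self.dropped)
        if overlap:
            raise ValueError(f"species both assigned and dropped: {sorted(overlap)}")
        if not 0 <= self.buffer_fraction < 0.5:
            raise ValueError("buffer_fraction must be in [0, 0.5)")

    @property
    def species(self) -> list:
        return sorted(self.values)

    def series(self) -> pd.Series:
        return pd.Series(self.values, dtype=int).sort_index()

    def report(self) -> dict:
        return {
            "statistic": self.statistic,
            "center": self.center,
            "buffer_fraction": self.buffer_fraction,
            "n_assigned": len(self.values),
            "n_dropped": len(self.dropped),
            "dropped": sorted(self.dropped),
        }


def binarize_by_center(
    values: Mapping[str, float], center: str = "median", buffer_fraction: float = 0.0
) -> BinaryTrait:
    """Split at the median (or mean), dropping a central rank-buffer zone.

    ``round(buffer_fraction * n)`` species nearest the center in rank order are
    dropped, symmetric by rank (ties broken by rank then name for determinism).
    Remaining species get 1 if value > center, else 0 (exact center -> 0).
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    if not 0 <= buffer_fraction < 0.5:
        raise ValueError("buffer_fraction must be in [0, 0.5)")
    clean = {k: float(v) for k, v in values.items() if v is not None and not pd.isna(v)}
    if len(clean) < 4:
        raise ValueError("need at least 4 non-missing values to binarize")
    vals = np.array(list(clean.values()))
    if np.allclose(vals, vals[0]):
        raise ValueError("all values identical; nothing to binarize")
    c = float(np.median(vals)) if center == "median" else float(vals.mean())
    n = len(clean)
    n_drop = int(round(buffer_fraction * n))
    # rank species by |rank position - center position|, symmetric buffer
    ordered = sorted(clean.items(), key=lambda kv: (kv[1], kv[0]))
    mid = (n - 1) / 2.0
    by_centrality = sorted(range(n), key=lambda i: (abs(i - mid), i))
    drop_idx = set(by_centrality[:n_drop])
    assigned = {}
    dropped = set()
    for i, (sp, v) in enumerate(ordered):
        if i in drop_idx:
            dropped.add(sp)
        else:
            assigned[sp] = 1 if v > c else 0
    return BinaryTrait(
        values=assigned,
        dropped=frozenset(dropped),
        statistic=center,
        center=c,
        buffer_fraction=buffer_fraction,
    )


def binarize_at_two(values: Mapping[str, float]) -> BinaryTrait:
    """Threshold at two: >= 2 -> 1 (polygyny/polyandry), < 2 -> 0. No buffer."""
    clean = {k: float(v) for k, v in values.items() if v is not None and not pd.isna(v)}
    if not clean:
        raise ValueError("no values to binarize")
    assigned = {sp: (1 if v >= 2 else 0) for sp, v in clean.items()}
    return BinaryTrait(
        values=assigned,
        dropped=frozenset(),
        statistic="fixed-two",
        center=2.0,
        buffer_fraction=0.0,
    )


def binarize_repro_potential(category: int, scheme: str) -> int:
    """Collapse the 4 reproductive-potential categories to a binary trait.

    scheme='sex': categories {1,2} (worker mating possible) -> 0, {3,4} -> 1.
    scheme='sterility': categories {1,2,3} -> 0, {4} (fully sterile) -> 1.
    """
    if category not in REPRO_CATEGORIES:
        raise ValueError(f"category must be in 1..4, got {category!r}")
    if scheme == "sex":
        return 0 if category in (1, 2) else 1
    if scheme == "sterility":
        return 0 if category in (1, 2, 3) else 1
    raise ValueError(f"unknown scheme {scheme!r}")
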