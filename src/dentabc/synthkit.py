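"""Synthetic specimen-level datasets with controlled demographic truth.

The generator emulates the structure of a compiled Ice Age dental trait
database: per-specimen ASUDAS expression grades over tooth fields with
realistic missingness, geographic/temporal metadata, plus modern
population frequency fixtures for polarity estimation.  Trait states are
generated by the coalescent module itself — each specimen is one sampled
lineage of its spatiotemporal group under the chosen demographic model —
so every downstream stage can be tested end-to-end against a known
truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import demography as dg
from .coalescent import (
    GROUP_ORDER,
    _derived_states,
    _simulate_genealogy,
    _single_site_states,
)
from .demography import ka_to_generations
from .polarity import WaypointRoute
from .trait_data import (
    EAST_COUNTRIES,
    PERIOD_BOUNDS_KA,
    TraitDefinition,
    TraitObservationMatrix,
    WEST_COUNTRIES,
)

__all__ = [
    "SyntheticTruth",
    "SyntheticDataset",
    "default_trait_definitions",
    "generate_synthetic_dataset",
    "generate_polarity_fixture",
]

# Coarse bounding boxes for plausible specimen coordinates per region.
_REGION_BOX = {
    "West": ((36.0, 52.0), (-9.0, 10.0)),
    "East": ((36.0, 56.0), (10.0, 40.0)),
}
_REGION_COUNTRIES = {
    "West": tuple(c for c in WEST_COUNTRIES if c not in ("United Kingdom", "Ireland")),
    "East": tuple(c for c in EAST_COUNTRIES if c != "Russia"),
}

_MAX_GRADE = 5


@dataclass(frozen=True)
class SyntheticTruth:
    """Full description of a synthetic dataset's generating process."""

    model_id: int
    specimens_per_group: Mapping[tuple[str, str], int]
    seed: int
    n_traits: int = 20
    missingness: float = 0.0        # per (specimen, tooth) drop probability
    block_missing: bool = False     # drop whole tooth fields together
    params: Mapping[str, float] | None = None  # drawn from priors if None
    mu: float | None = None                    # overrides params["mu"] if set
    # "single_site" keeps every generated trait polymorphic, as compiled
    # dental trait databases are; "poisson" allows fixed traits.
    mutation_mode: str = "single_site"

    def __post_init__(self):
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must be in [0, 1]")
        if all(n <= 0 for n in self.specimens_per_group.values()):
            raise ValueError("need at least one specimen in some group")
        if any(n < 0 for n in self.specimens_per_group.values()):
            raise ValueError("negative specimen count")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its generating truth."""

    grades: pd.DataFrame                 # specimen x "trait:tooth" ASUDAS grades
    matrix: TraitObservationMatrix      # dichotomized, modified-key reduced
    metadata: pd.DataFrame
    trait_definitions: list[TraitDefinition]
    truth: SyntheticTruth
    params: dict[str, float]
    true_frequencies: pd.DataFrame       # trait x group derived freq (pre-missingness)


def default_trait_definitions(n_traits: int = 20) -> list[TraitDefinition]:
    """A deterministic set of generic trait definitions.

    Tooth fields cycle through molar/premolar/incisor fields with
    three-tooth substitute orders and breakpoints between 1 and 3.
    All generated traits use ancestral = absence (presence is derived).
    """
    fields = [("M", ("M1", "M2", "M3")), ("P", ("P3", "P4")), ("I", ("I1", "I2"))]
    defs = []
    for i in range(n_traits):
        fname, order = fields[i % len(fields)]
        defs.append(
            TraitDefinition(
                trait_id=f"T{i + 1:02d}",
                tooth_field=f"{fname}{i + 1:02d}",
                key_tooth=order[0],
                substitute_order=order,
                breakpoint=1 + i % 3,
                polarity="absence",
            )
        )
    return defs


def _simulate_states(
    demog,
    counts: dict[tuple[str, str], int],
    mu: float,
    rng: np.random.Generator,
    mutation_mode: str = "single_site",
) -> dict[tuple[str, str], np.ndarray]:
    """Per-group boolean derived-state arrays, one entry per specimen."""
    import random as _random

    times = {p: ka_to_generations(t) for p, t in
             {"MPG": 37.5, "LPG": 21.35, "LG&EH": 10.85}.items()}
    injections = []
    spans = {}
    off = 0
    for g in GROUP_ORDER:
        n = counts.get(g, 0)
        if n == 0:
            continue
        injections.append((times[g[1]], demog.sample_demes[g], n))
        spans[g] = (off, off + n)
        off += n
    py_rng = _random.Random(int(rng.integers(0, 2**63)))
    parent, node_time, n_samp = _simulate_genealogy(demog, injections, py_rng)
    if mutation_mode == "single_site":
        derived = _single_site_states(parent, node_time, rng)
    else:
        derived = _derived_states(parent, node_time, mu, rng)
    return {g: derived[lo:hi] for g, (lo, hi) in spans.items()}


def generate_synthetic_dataset(
    truth: SyntheticTruth,
    trait_defs: Sequence[TraitDefinition] | None = None,
    priors: Mapping[str, dg.PriorSpec] | None = None,
) -> SyntheticDataset:
    """Generate a specimen-level dataset under a known demographic model.

    Each specimen is one sampled lineage of its group's coalescent
    genealogy, so trait states carry the model's drift, migration and
    replacement signal exactly.  Derived states map to presence
    (ancestral = absence for every generated trait); presence/absence is
    then expressed as an ASUDAS grade at or above / below the trait's
    breakpoint, and per-tooth missingness is applied independently (or
    per whole tooth field in block mode).
    """
    rng = np.random.default_rng(truth.seed)
    defs = list(trait_defs) if trait_defs is not None else default_trait_definitions(
        truth.n_traits
    )
    if priors is None:
        priors = dg.default_priors()
    params = dict(truth.params) if truth.params is not None else dg.draw_parameters(
        priors, rng
    )
    if truth.mu is not None:
        params["mu"] = truth.mu
    model = dg.build_model(truth.model_id)
    demog = model.realize(params)
    counts = {g: int(n) for g, n in truth.specimens_per_group.items() if n > 0}

    # specimen metadata
    sids = []
    meta_rows = []
    group_of = {}
    for region, period in GROUP_ORDER:
        n = counts.get((region, period), 0)
        older, younger = PERIOD_BOUNDS_KA[period]
        (lat_lo, lat_hi), (lon_lo, lon_hi) = _REGION_BOX[region]
        pool = _REGION_COUNTRIES[region]
        for i in range(n):
            sid = f"S{len(sids) + 1:04d}"
            sids.append(sid)
            group_of[sid] = (region, period)
            meta_rows.append(
                {
                    "id": sid,
                    "country": pool[int(rng.integers(len(pool)))],
                    "latitude": float(rng.uniform(lat_lo, lat_hi)),
                    "longitude": float(rng.uniform(lon_lo, lon_hi)),
                    # strictly inside the period so the tie rule is untouched
                    "age_mean": float(rng.uniform(younger + 1e-6, older - 1e-6)),
                }
            )
    metadata = pd.DataFrame(meta_rows).set_index("id")

    # trait states via the coalescent, one genealogy per trait
    grade_cols: dict[str, np.ndarray] = {}
    freq_rows = []
    present = pd.DataFrame(index=metadata.index, dtype=float)
    for d in defs:
        states = _simulate_states(
            demog, counts, params["mu"], rng, mutation_mode=truth.mutation_mode
        )
        row = {"trait": d.trait_id}
        flat = np.zeros(len(sids), bool)
        off = 0
        for g in GROUP_ORDER:
            n = counts.get(g, 0)
            if n == 0:
                row[f"{g[0]}|{g[1]}"] = np.nan
                continue
            flat[off : off + n] = states[g]
            row[f"{g[0]}|{g[1]}"] = float(states[g].mean())
            off += n
        freq_rows.append(row)
        present[d.trait_id] = flat.astype(float)

        # ASUDAS grades per tooth: present -> grade in [breakpoint, max],
        # absent -> grade in [0, breakpoint)
        lo = rng.integers(0, d.breakpoint, size=len(sids))
        hi = rng.integers(d.breakpoint, _MAX_GRADE + 1, size=len(sids))
        grade = np.where(flat, hi, lo).astype(float)
        if truth.block_missing:
            drop_field = rng.random(len(sids)) < truth.missingness
        for tooth in d.substitute_order:
            if truth.block_missing:
                drop = drop_field
            else:
                drop = rng.random(len(sids)) < truth.missingness
            col = grade.copy()
            col[drop] = np.nan
            grade_cols[f"{d.trait_id}:{tooth}"] = col

    grades = pd.DataFrame(grade_cols, index=metadata.index)

    # dichotomized + modified-key view, dropping empty specimens
    from .trait_data import dichotomize_scores, reduce_to_key_teeth

    binary = dichotomize_scores(grades, defs)
    reduced = reduce_to_key_teeth(binary, defs, mode="modified_key")
    keep = reduced.notna().any(axis=1)
    matrix = TraitObservationMatrix(reduced[keep], metadata[keep])

    true_frequencies = pd.DataFrame(freq_rows).set_index("trait")
    return SyntheticDataset(
        grades=grades,
        matrix=matrix,
        metadata=metadata,
        trait_definitions=defs,
        truth=truth,
        params=params,
        true_frequencies=true_frequencies,
    )


def generate_polarity_fixture(
    n_pops: int,
    slopes_per_km: Sequence[float],
    noise_sd: float,
    seed: int,
    max_distance_km: float = 25_000.0,
    intercepts: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.Series, WaypointRoute]:
    """Modern-population frequencies along a synthetic out-of-Africa route.

    Populations sit at evenly spaced routed distances; each trait ``i``
    has presence frequency ``intercept_i + slope_i * distance`` plus
    Gaussian noise, clipped to [0, 1].  Returns (frequency table indexed
    by population with latitude/longitude columns, outgroup frequency
    series at distance 0, synthetic route).  The outgroup frequency is
    the noiseless cline value at the origin.
    """
    if n_pops < 3:
        raise ValueError("need at least three populations")
    rng = np.random.default_rng(seed)
    slopes = np.asarray(list(slopes_per_km), float)
    if intercepts is None:
        intercepts = np.where(slopes < 0, 0.9, 0.1)
    intercepts = np.asarray(list(intercepts), float)
    distances = np.linspace(0.0, max_distance_km, n_pops + 1)[1:]
    # a due-north synthetic route: 1 deg latitude ~ 111.19 km
    km_per_deg = np.pi * 6371.0 / 180.0
    origin = (0.0, 0.0)
    lats = np.clip(distances / km_per_deg, 0, 89.9)
    rows = {}
    freqs = {}
    for i, d in enumerate(distances):
        pid = f"POP{i + 1:02d}"
        rows[pid] = {"latitude": float(lats[i]), "longitude": 0.0, "path": "route"}
        freqs[pid] = np.clip(
            intercepts + slopes * d + rng.normal(0.0, noise_sd, len(slopes)), 0.0, 1.0
        )
    traits = [f"T{i + 1:02d}" for i in range(len(slopes))]
    table = pd.DataFrame(rows).T
    freq_df = pd.DataFrame(
        {t: [freqs[p][i] for p in table.index] for i, t in enumerate(traits)},
        index=table.index,
    )
    out = pd.concat([table, freq_df], axis=1)
    outgroup = pd.Series(np.clip(intercepts, 0.0, 1.0), index=traits, name="outgroup")
    route = WaypointRoute(origin=origin, waypoints=())
    return out, outgroup, route
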