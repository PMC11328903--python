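"""Structured-coalescent simulation of single biallelic trait frequencies.

Each dental trait is treated as a single neutral locus.  For one trait,
one lineage per sampled specimen enters the genealogy at its
spatiotemporal group's sampling time (by default the midpoint of the
group's climate period); lineages then coalesce, migrate and move
between demes backward in time according to a
:class:`~dentabc.demography.RealizedDemography` until a single common
ancestor remains.  Mutations are dropped on branches as a Poisson
process at rate ``mu`` per lineage per generation; a sampled lineage
carries the derived state iff at least one mutation lies on its path to
the root (infinite-alleles reading, no back mutation).  The per-group
derived-state frequency is the summary statistic.

Reference tables stack one flat summary vector per simulation, labelled
by the generating model, with the column layout mirroring the observed
data: one column per unmasked (trait, group) cell, sample sizes equal to
the observed counts, and no column at all where the observed data have
none.
"""

from __future__ import annotations

import json
import math
import random
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import (
    DemographicModel,
    PriorSpec,
    RealizedDemography,
    build_model,
    draw_parameters,
    ka_to_generations,
    N_ANCESTRAL,
)

__all__ = [
    "DEFAULT_SAMPLING_TIMES_KA",
    "GROUP_ORDER",
    "SampleConfig",
    "ReferenceTable",
    "simulate_trait_frequencies",
    "build_reference_table",
    "emit_ms_command",
    "parse_ms_command",
    "validate_alignment",
    "AlignmentReport",
]

#: Canonical ordering of the six spatiotemporal groups in flat vectors.
GROUP_ORDER: tuple[tuple[str, str], ...] = (
    ("West", "MPG"),
    ("West", "LPG"),
    ("West", "LG&EH"),
    ("East", "MPG"),
    ("East", "LPG"),
    ("East", "LG&EH"),
)

#: Default lineage sampling times: the midpoint of each climate period.
DEFAULT_SAMPLING_TIMES_KA = {"MPG": 37.5, "LPG": 21.35, "LG&EH": 10.85}

_INF = math.inf


@dataclass(frozen=True)
class SampleConfig:
    """Per-cell lineage counts and per-group sampling times for one dataset.

    ``counts`` maps (trait, (region, period)) to the number of lineages to
    sample, mirroring the observed sample size for that cell; cells that
    are absent or have count 0 are masked and produce no summary column.
    """

    traits: tuple[str, ...]
    counts: Mapping[tuple[str, tuple[str, str]], int]
    sampling_times_gen: Mapping[str, float] = field(
        default_factory=lambda: {
            p: ka_to_generations(t) for p, t in DEFAULT_SAMPLING_TIMES_KA.items()
        }
    )

    def __post_init__(self):
        for key, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative lineage count for cell {key}")

    @classmethod
    def uniform(
        cls,
        traits: Sequence[str],
        n_per_cell: int,
        groups: Sequence[tuple[str, str]] = GROUP_ORDER,
        sampling_times_ka: Mapping[str, float] | None = None,
    ) -> "SampleConfig":
        counts = {(t, g): n_per_cell for t in traits for g in groups}
        kwargs = {}
        if sampling_times_ka is not None:
            kwargs["sampling_times_gen"] = {
                p: ka_to_generations(t) for p, t in sampling_times_ka.items()
            }
        return cls(tuple(traits), counts, **kwargs)

    @classmethod
    def from_grouped_table(cls, table) -> "SampleConfig":
        """Build from a :class:`~dentabc.trait_data.GroupedFrequencyTable`."""
        counts = {
            (trait, group): int(n)
            for (trait, group), n in table.n_observed_items()
            if n > 0
        }
        return cls(tuple(table.traits), counts)

    def layout(self) -> list[tuple[str, tuple[str, str]]]:
        """Canonical unmasked-cell order: traits in order, groups in
        :data:`GROUP_ORDER`."""
        return [
            (t, g)
            for t in self.traits
            for g in GROUP_ORDER
            if self.counts.get((t, g), 0) > 0
        ]

    def group_counts(self, trait: str) -> dict[tuple[str, str], int]:
        return {
            g: self.counts.get((trait, g), 0)
            for g in GROUP_ORDER
            if self.counts.get((trait, g), 0) > 0
        }


# ---------------------------------------------------------------------------
# Core genealogy simulator
# ---------------------------------------------------------------------------


def _coal_waiting_time(k: int, seg, t: float, rng: random.Random) -> float:
    """Waiting time to next coalescence among k lineages from time t,
    within a single exponential-size segment (may exceed the segment)."""
    c = k * (k - 1) * 0.5
    g = seg.growth
    n_now = seg.n_lo * math.exp(g * (t - seg.t_lo))
    a = c / n_now  # hazard at t
    e = rng.expovariate(1.0)
    if g == 0.0:
        return e / a
    z = 1.0 - g * e / a
    if z <= 0.0:
        return _INF
    return -math.log(z) / g


def _simulate_genealogy(
    demog: RealizedDemography,
    injections: Sequence[tuple[float, str, int]],
    rng: random.Random,
) -> tuple[list[int], list[float], int]:
    """Simulate one genealogy; returns (parent, node_time, n_samples).

    ``injections`` lists (time_gen, deme, count) for sampled lineages;
    sample nodes occupy indices 0..n_samples-1 in injection order.
    Parents always have a larger node index than their children; the root
    is the last node and has parent -1.
    """
    n_samples = sum(c for _, _, c in injections)
    if n_samples < 2:
        raise ValueError("need at least two sampled lineages in total")

    parent: list[int] = [-1] * n_samples
    node_time: list[float] = [0.0] * n_samples
    active: dict[str, list[int]] = {name: [] for name in demog.demes}

    # Timeline of discrete happenings: injections before moves on ties.
    # Sample node ids follow the caller's injection order (callers rely on
    # this to attribute index ranges to groups), not the time order.
    timeline: list[tuple[float, int, object]] = []
    nid = 0
    for t_s, deme, count in injections:
        if deme not in active:
            raise ValueError(f"unknown sample deme {deme!r}")
        timeline.append((t_s, 0, (deme, list(range(nid, nid + count)))))
        for i in range(nid, nid + count):
            node_time[i] = t_s
        nid += count
    for mv in demog.moves:
        timeline.append((mv.time, 1, mv))
    timeline.sort(key=lambda x: (x[0], x[1]))

    # Interval cut points: every time at which rates may change.
    cuts: set[float] = {t for t, _, _ in timeline}
    for deme in demog.demes.values():
        for seg in deme.segments:
            if math.isfinite(seg.t_hi):
                cuts.add(seg.t_hi)
            cuts.add(seg.t_lo)
    for ep in demog.migrations:
        cuts.add(ep.t_lo)
        cuts.add(ep.t_hi)
    cut_list = sorted(cuts)

    t = timeline[0][0]
    ti = 0  # next timeline entry
    n_active = 0
    pending = n_samples
    expovariate = rng.expovariate
    rnd = rng.random

    while True:
        # Apply all discrete happenings at the current time.
        while ti < len(timeline) and timeline[ti][0] <= t:
            _, kind, payload = timeline[ti]
            ti += 1
            if kind == 0:
                deme, ids = payload
                active[deme].extend(ids)
                n_active += len(ids)
                pending -= len(ids)
            else:
                mv = payload
                src = active[mv.source]
                if src:
                    if len(mv.dests) == 1:
                        active[mv.dests[0][0]].extend(src)
                    else:
                        thresholds = []
                        acc = 0.0
                        for dest, prob in mv.dests:
                            acc += prob
                            thresholds.append((acc, dest))
                        for lid in src:
                            u = rnd()
                            for acc, dest in thresholds:
                                if u <= acc:
                                    active[dest].append(lid)
                                    break
                            else:
                                active[mv.dests[-1][0]].append(lid)
                    active[mv.source] = []
        if n_active <= 1 and pending == 0:
            break

        ci = bisect_right(cut_list, t)
        t_end = cut_list[ci] if ci < len(cut_list) else _INF

        # Migration pairs active in (t, t_end); the epoch list is short,
        # so a linear scan per interval is cheap.
        mig_pairs = []
        for ep in demog.migrations:
            if ep.t_lo <= t < ep.t_hi:
                mig_pairs.extend(ep.pairs)

        # Run the in-interval event loop.
        while True:
            best_dt = _INF
            best_deme = None
            for name, lin in active.items():
                k = len(lin)
                if k >= 2:
                    seg = demog.demes[name].segment_at(t)
                    dt = _coal_waiting_time(k, seg, t, rng)
                    if dt < best_dt:
                        best_dt = dt
                        best_deme = name
            mig_total = 0.0
            if mig_pairs:
                for src, dst, rate in mig_pairs:
                    mig_total += len(active[src]) * rate
                if mig_total > 0.0:
                    dt = expovariate(mig_total)
                    if dt < best_dt:
                        best_dt = dt
                        best_deme = None  # signals migration
            if t + best_dt >= t_end:
                t = t_end
                break
            if best_dt == _INF:
                if pending == 0 and n_active > 1:
                    raise RuntimeError(
                        "lineages cannot reach a common ancestor: no further "
                        "coalescence, migration or scheduled event"
                    )
                t = t_end
                break
            t += best_dt
            if best_deme is not None:
                lin = active[best_deme]
                k = len(lin)
                i = int(rnd() * k)
                j = int(rnd() * (k - 1))
                if j >= i:
                    j += 1
                a, b = lin[i], lin[j]
                new = len(parent)
                parent.append(-1)
                node_time.append(t)
                parent[a] = new
                parent[b] = new
                if i < j:
                    lin[j] = lin[-1]
                    lin[i] = new
                else:
                    lin[i] = lin[-1]
                    lin[j] = new
                lin.pop()
                n_active -= 1
                if n_active <= 1 and pending == 0:
                    return parent, node_time, n_samples
            else:
                u = rnd() * mig_total
                acc = 0.0
                for src, dst, rate in mig_pairs:
                    acc += len(active[src]) * rate
                    if u <= acc:
                        lin = active[src]
                        idx = int(rnd() * len(lin))
                        lid = lin[idx]
                        lin[idx] = lin[-1]
                        lin.pop()
                        active[dst].append(lid)
                        break

        if t == _INF and (n_active > 1 or pending > 0):
            raise RuntimeError(
                "lineages cannot reach a common ancestor: schedule exhausted"
            )

    return parent, node_time, n_samples


def _derived_states(
    parent: list[int],
    node_time: list[float],
    mu: float,
    np_rng: np.random.Generator,
) -> np.ndarray:
    """Boolean derived flag per sample given Poisson(mu * branch) mutations."""
    n = len(parent)
    par = np.asarray(parent)
    tt = np.asarray(node_time)
    branch = np.where(par >= 0, tt[np.clip(par, 0, n - 1)] - tt, 0.0)
    p_mut = -np.expm1(-mu * branch)
    mut = (np_rng.random(n) < p_mut).tolist()
    derived = [False] * n
    # parents always have larger indices; sweep root -> tips
    for i in range(n - 2, -1, -1):
        derived[i] = derived[parent[i]] or mut[i]
    return np.asarray(derived)


def _single_site_states(
    parent: list[int],
    node_time: list[float],
    np_rng: np.random.Generator,
) -> np.ndarray:
    """Derived flags when exactly one segregating mutation is placed on a
    branch drawn proportional to branch length (the ms ``-s 1`` reading
    of a single polymorphic trait; the pooled sample is always
    polymorphic and the mutation rate cancels out)."""
    n = len(parent)
    par = np.asarray(parent)
    tt = np.asarray(node_time)
    branch = np.where(par >= 0, tt[np.clip(par, 0, n - 1)] - tt, 0.0)
    edge = int(np_rng.choice(n, p=branch / branch.sum()))
    derived = [False] * n
    derived[edge] = True
    for i in range(n - 2, -1, -1):
        if not derived[i]:
            derived[i] = derived[parent[i]]
    derived[edge] = True
    return np.asarray(derived)


MUTATION_MODES = ("poisson", "conditioned", "single_site")


def simulate_trait_frequencies(
    demog: RealizedDemography,
    counts: Mapping[tuple[str, str], int],
    mu: float,
    rng: np.random.Generator,
    sampling_times_gen: Mapping[str, float] | None = None,
    condition_on_segregating: bool = False,
    mutation_mode: str = "poisson",
    max_tries: int = 10_000,
) -> dict[tuple[str, str], float]:
    """Simulate one trait; return derived-state frequency per sampled group.

    ``counts`` maps (region, period) to the lineage count for that group;
    groups with zero count are masked and yield no frequency.

    Mutation modes (interpretations of "a single polymorphic trait"):

    ``"poisson"``
        Mutations fall as a Poisson process at rate ``mu`` per lineage per
        generation; monomorphic outcomes (frequencies 0/1) are retained.
    ``"conditioned"``
        As ``"poisson"`` but the genealogy+mutation draw is rejected and
        redrawn until the pooled sample is polymorphic (impractical when
        ``mu`` times the tree depth is large).
    ``"single_site"``
        Exactly one segregating mutation placed on a branch drawn
        proportional to its length; ``mu`` cancels out of the outcome.

    ``condition_on_segregating=True`` is shorthand for the
    ``"conditioned"`` mode.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if condition_on_segregating and mutation_mode == "poisson":
        mutation_mode = "conditioned"
    if mutation_mode not in MUTATION_MODES:
        raise ValueError(f"unknown mutation mode {mutation_mode!r}")
    condition_on_segregating = mutation_mode == "conditioned"
    if sampling_times_gen is None:
        sampling_times_gen = {
            p: ka_to_generations(t) for p, t in DEFAULT_SAMPLING_TIMES_KA.items()
        }
    groups = [g for g in GROUP_ORDER if counts.get(g, 0) > 0]
    extra = set(counts) - set(GROUP_ORDER)
    if extra:
        raise ValueError(f"unknown groups in sample counts: {sorted(extra)}")
    total = sum(counts[g] for g in groups)
    if total < 2:
        raise ValueError("need at least two lineages in total")

    injections = []
    spans: dict[tuple[str, str], tuple[int, int]] = {}
    offset = 0
    for g in groups:
        region, period = g
        deme = demog.sample_demes[(region, period)]
        n_g = counts[g]
        injections.append((sampling_times_gen[period], deme, n_g))
        spans[g] = (offset, offset + n_g)
        offset += n_g

    py_rng = random.Random(int(rng.integers(0, 2**63)))
    for _ in range(max_tries if condition_on_segregating else 1):
        parent, node_time, n_samp = _simulate_genealogy(demog, injections, py_rng)
        if mutation_mode == "single_site":
            derived = _single_site_states(parent, node_time, rng)
        else:
            derived = _derived_states(parent, node_time, mu, rng)
        n_der = int(derived[:n_samp].sum())
        if not condition_on_segregating or 0 < n_der < n_samp:
            break
    else:
        raise RuntimeError(
            f"no segregating draw in {max_tries} tries (mu={mu:g})"
        )

    return {
        g: float(derived[lo:hi].mean()) for g, (lo, hi) in spans.items()
    }


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Simulated summary vectors labelled by generating model.

    ``summaries`` has one row per simulation and one column per unmasked
    (trait, group) cell in the canonical layout shared with the observed
    vector.
    """

    summaries: np.ndarray
    model_ids: np.ndarray
    params: pd.DataFrame
    layout: list[tuple[str, tuple[str, str]]]
    meta: dict

    def __post_init__(self):
        if self.summaries.shape[0] != len(self.model_ids):
            raise ValueError("row count mismatch between summaries and labels")
        if self.summaries.shape[1] != len(self.layout):
            raise ValueError("column count does not match layout")

    @property
    def n_rows(self) -> int:
        return self.summaries.shape[0]

    @property
    def models(self) -> list[int]:
        return sorted(set(int(m) for m in self.model_ids))

    def subset(self, model_ids: Iterable[int]) -> "ReferenceTable":
        wanted = set(int(m) for m in model_ids)
        missing = wanted - set(self.models)
        if missing:
            raise ValueError(f"models absent from reference table: {sorted(missing)}")
        mask = np.isin(self.model_ids, sorted(wanted))
        return ReferenceTable(
            summaries=self.summaries[mask],
            model_ids=self.model_ids[mask],
            params=self.params.loc[mask].reset_index(drop=True),
            layout=list(self.layout),
            meta={**self.meta, "subset_of": self.meta.get("models")},
        )

    def column_names(self) -> list[str]:
        return [f"{t}|{r}|{p}" for t, (r, p) in self.layout]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.summaries, columns=self.column_names())
        df.insert(0, "model", self.model_ids)
        return pd.concat([df, self.params.reset_index(drop=True)], axis=1)

    def save(self, path_prefix: str) -> None:
        """Write ``<prefix>.csv`` plus a ``<prefix>.meta.json`` sidecar."""
        self.to_dataframe().to_csv(f"{path_prefix}.csv", index=False)
        sidecar = {
            "layout": [[t, r, p] for t, (r, p) in self.layout],
            "param_names": list(self.params.columns),
            "meta": self.meta,
        }
        with open(f"{path_prefix}.meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str) -> "ReferenceTable":
        with open(f"{path_prefix}.meta.json") as fh:
            sidecar = json.load(fh)
        df = pd.read_csv(f"{path_prefix}.csv")
        layout = [(t, (r, p)) for t, r, p in sidecar["layout"]]
        cols = [f"{t}|{r}|{p}" for t, (r, p) in layout]
        return cls(
            summaries=df[cols].to_numpy(float),
            model_ids=df["model"].to_numpy(int),
            params=df[sidecar["param_names"]].copy(),
            layout=layout,
            meta=sidecar["meta"],
        )


def build_reference_table(
    models: Sequence[DemographicModel | int],
    priors: Mapping[str, PriorSpec],
    sample_config: SampleConfig,
    n_per_model: int,
    seed: int,
    prior_overrides: Mapping[str, float | PriorSpec] | None = None,
    condition_on_segregating: bool = False,
    mutation_mode: str = "poisson",
    model_labels: Sequence[int] | None = None,
) -> ReferenceTable:
    """Simulate ``n_per_model`` summary rows per model.

    Each row draws one shared parameter vector (including ``mu``) and
    simulates every trait's genealogy independently with the observed
    per-cell sample sizes.  Row ``(model, i)`` has its own RNG substream,
    so any row is reproducible in isolation.  ``model_labels`` optionally
    relabels the generating models in the output (used e.g. to pit two
    configurations of the same model against each other).
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    models = [m if isinstance(m, DemographicModel) else build_model(m) for m in models]
    if model_labels is None:
        labels = [m.model_id for m in models]
    else:
        labels = list(model_labels)
        if len(labels) != len(models):
            raise ValueError("model_labels length mismatch")
    layout = sample_config.layout()
    if not layout:
        raise ValueError("sample configuration has no unmasked cells")
    trait_counts = {t: sample_config.group_counts(t) for t in sample_config.traits}

    rows = np.empty((len(models) * n_per_model, len(layout)))
    row_models = np.empty(len(models) * n_per_model, dtype=int)
    param_rows = []
    r = 0
    for label, model in zip(labels, models):
        for i in range(n_per_model):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, model.model_id, label, i])
            )
            params = draw_parameters(priors, rng, overrides=prior_overrides)
            demog = model.realize(params)
            freqs: dict[tuple[str, tuple[str, str]], float] = {}
            for trait in sample_config.traits:
                counts = trait_counts[trait]
                if not counts:
                    continue
                f = simulate_trait_frequencies(
                    demog,
                    counts,
                    mu=params["mu"],
                    rng=rng,
                    sampling_times_gen=sample_config.sampling_times_gen,
                    condition_on_segregating=condition_on_segregating,
                    mutation_mode=mutation_mode,
                )
                for g, v in f.items():
                    freqs[(trait, g)] = v
            rows[r] = [freqs[cell] for cell in layout]
            row_models[r] = label
            param_rows.append(params)
            r += 1
    return ReferenceTable(
        summaries=rows,
        model_ids=row_models,
        params=pd.DataFrame(param_rows),
        layout=layout,
        meta={
            "models": sorted(set(labels)),
            "n_per_model": n_per_model,
            "seed": seed,
            "condition_on_segregating": condition_on_segregating,
            "mutation_mode": mutation_mode,
            "prior_overrides": {
                k: (v if not isinstance(v, PriorSpec)
                    else [v.distribution, v.minimum, v.maximum])
                for k, v in (prior_overrides or {}).items()
            },
        },
    )


# ---------------------------------------------------------------------------
# Alignment validation
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    ok: bool
    problems: list[str]

    def __bool__(self) -> bool:
        return self.ok


def validate_alignment(
    rt: ReferenceTable,
    observed: Sequence[float],
    layout: Sequence[tuple[str, tuple[str, str]]],
) -> AlignmentReport:
    """Check that a reference table and an observed vector are comparable:
    identical column layouts and all frequencies within [0, 1]."""
    problems: list[str] = []
    rt_layout = list(rt.layout)
    layout = [(t, tuple(g)) for t, g in layout]
    if rt_layout != layout:
        extra = [c for c in layout if c not in rt_layout]
        missing = [c for c in rt_layout if c not in layout]
        if extra:
            problems.append(f"cells absent from reference table: {extra[:5]}")
        if missing:
            problems.append(f"cells absent from observed vector: {missing[:5]}")
        if not extra and not missing:
            problems.append("cell order differs between layouts")
    if len(observed) != len(layout):
        problems.append(
            f"observed vector length {len(observed)} != layout size {len(layout)}"
        )
    else:
        obs = np.asarray(observed, float)
        bad = np.flatnonzero((obs < 0) | (obs > 1) | ~np.isfinite(obs))
        for i in bad[:5]:
            problems.append(f"observed frequency out of [0,1] at column {i} ({layout[i]})")
    bad_rows, bad_cols = np.where(
        (rt.summaries < 0) | (rt.summaries > 1) | ~np.isfinite(rt.summaries)
    )
    for rr, cc in list(zip(bad_rows, bad_cols))[:5]:
        problems.append(
            f"reference-table frequency out of [0,1] at row {rr}, column {cc}"
        )
    return AlignmentReport(ok=not problems, problems=problems)


# ---------------------------------------------------------------------------
# Hudson ms dialect emission (external cross-validation only)
# ---------------------------------------------------------------------------


def emit_ms_command(
    model: DemographicModel | RealizedDemography,
    params: Mapping[str, float] | None,
    sample_config: SampleConfig,
    n0: float = N_ANCESTRAL,
) -> str:
    """Emit a deterministic Hudson-ms-dialect command for one trait's
    demography (sizes scaled by ``n0``, migration as ``4*n0*m``, times in
    units of ``4*n0`` generations).

    The ms dialect cannot express serial (ancient) sampling, so all
    lineages are emitted at time 0 and an explicit approximation note is
    appended as a shell comment.
    """
    demog = model.realize(params) if isinstance(model, DemographicModel) else model
    mu = (params or {}).get("mu", 0.0)
    trait = sample_config.traits[0]
    counts = sample_config.group_counts(trait)

    deme_names = sorted(demog.demes)
    idx = {name: i + 1 for i, name in enumerate(deme_names)}
    per_deme = {name: 0 for name in deme_names}
    serial = False
    for (region, period), n in counts.items():
        per_deme[demog.sample_demes[(region, period)]] += n
        if sample_config.sampling_times_gen[period] != 0:
            serial = True
    nsam = sum(per_deme.values())
    scale_t = 1.0 / (4.0 * n0)

    def f(x: float) -> str:
        return format(x, ".10g")

    parts = ["ms", str(nsam), "1", "-t", f(4.0 * n0 * mu)]
    parts += ["-I", str(len(deme_names))] + [str(per_deme[n]) for n in deme_names]
    events: list[tuple[float, list[str]]] = []
    for name in deme_names:
        deme = demog.demes[name]
        seg0 = deme.segments[0]
        parts += ["-n", str(idx[name]), f(seg0.n_lo / n0)]
        if seg0.growth != 0.0:
            # ms alpha: N(t)=x*exp(-alpha*t) with t in 4n0 units (backward)
            parts += ["-g", str(idx[name]), f(-seg0.growth * 4.0 * n0)]
        for seg in deme.segments[1:]:
            events.append(
                (seg.t_lo, ["-en", f(seg.t_lo * scale_t), str(idx[name]), f(seg.n_lo / n0)])
            )
            if seg.growth != 0.0:
                events.append(
                    (seg.t_lo, ["-eg", f(seg.t_lo * scale_t), str(idx[name]),
                                f(-seg.growth * 4.0 * n0)])
                )
    for ep in demog.migrations:
        for src, dst, rate in ep.pairs:
            events.append(
                (ep.t_lo, ["-em", f(ep.t_lo * scale_t), str(idx[src]), str(idx[dst]),
                           f(4.0 * n0 * rate)])
            )
            events.append(
                (ep.t_hi, ["-em", f(ep.t_hi * scale_t), str(idx[src]), str(idx[dst]), "0"])
            )
    n_extra = 0
    for mv in demog.moves:
        if len(mv.dests) == 1:
            events.append(
                (mv.time, ["-ej", f(mv.time * scale_t), str(idx[mv.source]),
                           str(idx[mv.dests[0][0]])])
            )
        else:
            # -es splits source: fraction p stays, 1-p founds a new deme.
            (d1, p1), (d2, _) = mv.dests
            n_extra += 1
            new_idx = len(deme_names) + n_extra
            events.append(
                (mv.time, ["-es", f(mv.time * scale_t), str(idx[mv.source]), f(p1)])
            )
            events.append(
                (mv.time, ["-ej", f(mv.time * scale_t), str(idx[mv.source]), str(idx[d1])])
            )
            events.append(
                (mv.time, ["-ej", f(mv.time * scale_t), str(new_idx), str(idx[d2])])
            )
    events.sort(key=lambda e: (e[0], e[1]))
    for _, flag in events:
        parts += flag
    cmd = " ".join(parts)
    if serial:
        cmd += "  # NOTE: serial sampling approximated as contemporaneous (t=0)"
    return cmd


def parse_ms_command(cmd: str, n0: float = N_ANCESTRAL) -> dict:
    """Parse a command emitted by :func:`emit_ms_command` back into
    unscaled quantities (sizes in gene copies, times in generations)."""
    cmd = cmd.split("#")[0].strip()
    tok = cmd.split()
    if tok[0] != "ms":
        raise ValueError("not an ms command")
    out: dict = {
        "nsam": int(tok[1]),
        "nreps": int(tok[2]),
        "theta": None,
        "npop": 1,
        "counts": [],
        "events": [],
        "initial_sizes": {},
        "initial_growth": {},
    }
    i = 3
    t4 = 4.0 * n0
    while i < len(tok):
        flag = tok[i]
        if flag == "-t":
            out["theta"] = float(tok[i + 1])
            i += 2
        elif flag == "-I":
            npop = int(tok[i + 1])
            out["npop"] = npop
            out["counts"] = [int(x) for x in tok[i + 2 : i + 2 + npop]]
            i += 2 + npop
        elif flag == "-n":
            out["initial_sizes"][int(tok[i + 1])] = float(tok[i + 2]) * n0
            i += 3
        elif flag == "-g":
            out["initial_growth"][int(tok[i + 1])] = -float(tok[i + 2]) / t4
            i += 3
        elif flag == "-en":
            out["events"].append(
                ("size", float(tok[i + 1]) * t4, int(tok[i + 2]), float(tok[i + 3]) * n0)
            )
            i += 4
        elif flag == "-eg":
            out["events"].append(
                ("growth", float(tok[i + 1]) * t4, int(tok[i + 2]), -float(tok[i + 3]) / t4)
            )
            i += 4
        elif flag == "-em":
            out["events"].append(
                ("migration", float(tok[i + 1]) * t4, int(tok[i + 2]), int(tok[i + 3]),
                 float(tok[i + 4]) / t4)
            )
            i += 5
        elif flag == "-ej":
            out["events"].append(
                ("join", float(tok[i + 1]) * t4, int(tok[i + 2]), int(tok[i + 3]))
            )
            i += 4
        elif flag == "-es":
            out["events"].append(
                ("split", float(tok[i + 1]) * t4, int(tok[i + 2]), float(tok[i + 3]))
            )
            i += 4
        else:
            raise ValueError(f"unrecognized ms flag {flag!r}")
    return out
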