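"""Backward-time demographic models of Upper Paleolithic Europe.

Fourteen alternative scenarios of Ice Age hunter-gatherer population history
are expressed as structured-coalescent event schedules over two sampled
regions (West, East) plus auxiliary demes (doomed predecessors, incoming
replacement populations, unsampled ghosts) and a shared ancestral deme.

The scenarios fall into three categories:

``Continuity`` (models 1-3)
    Uninterrupted presence in both regions.  Model 1 has bidirectional
    West-East migration in all three climate periods; model 2 drops
    migration during the Late Pleniglacial (LPG); model 3 additionally
    imposes a Last Glacial Maximum (LGM, 26.5-19 ka) bottleneck in which
    each region is reduced to a proportion ``P_lgm`` of its pre-LGM size.

``DiscontinuityWest`` (models 4-7)
    As model 3, but the West is replaced by an incoming population
    diverging from the East: at 14.7 ka (model 4, divergence ``T_s1``),
    at 28 ka (model 5, divergence ``T_s2``), at both times (model 6), or
    as model 6 with no Middle Pleniglacial (MPG) migration (model 7).

``DiscontinuityEast`` (models 8-14)
    As model 3, but the East is replaced by populations diverging from
    the West and/or from unsampled ghost demes; see :func:`build_model`.

All sizes are effective numbers of gene copies (one lineage per sampled
specimen); coalescence within a deme of size ``N`` occurs at rate
``k(k-1)/2 / N`` per generation for ``k`` lineages.  Time is measured in
generations before present with a fixed generation time of 25 years; the
two regions emerge from an ancestral deme of constant size 5000 at 47 ka.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "GENERATION_TIME_YEARS",
    "N_ANCESTRAL",
    "PriorSpec",
    "SizeSegment",
    "Deme",
    "MigrationEpoch",
    "LineageMove",
    "RealizedDemography",
    "DemographicModel",
    "MODEL_CATEGORIES",
    "DEFAULT_CATEGORIES",
    "build_model",
    "all_models",
    "default_priors",
    "load_priors",
    "draw_parameters",
    "ka_to_generations",
]

GENERATION_TIME_YEARS = 25.0
N_ANCESTRAL = 5000.0

#: Study window and climate-period boundaries, thousand years before present.
ROOT_TIME_KA = 47.0
LGM_START_KA = 26.5
LGM_END_KA = 19.0
PERIOD_BOUNDS_KA = {
    "MPG": (47.0, 28.0),
    "LPG": (28.0, 14.7),
    "LG&EH": (14.7, 7.0),
}

_INF = math.inf


def ka_to_generations(t_ka: float) -> float:
    """Convert thousand years before present to generations (25 yr each)."""
    if t_ka < 0:
        raise ValueError(f"time must be non-negative, got {t_ka} ka")
    return t_ka * 1000.0 / GENERATION_TIME_YEARS


# Fixed boundary times in generations.
T47 = ka_to_generations(47.0)     # 1880: regional demes emerge
T37 = ka_to_generations(37.0)
T28 = ka_to_generations(28.0)     # 1120: MPG/LPG boundary
T265 = ka_to_generations(26.5)    # 1060: LGM onset
T19 = ka_to_generations(19.0)     # 760: LGM end
T147 = ka_to_generations(14.7)    # 588: LPG/LG&EH boundary
T7 = ka_to_generations(7.0)       # 280: youngest end of study window


@dataclass(frozen=True)
class PriorSpec:
    """A uniform or log-uniform prior over one scalar model parameter."""

    name: str
    distribution: str  # "uniform" | "loguniform"
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "loguniform"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not self.minimum < self.maximum:
            raise ValueError(f"{self.name}: require minimum < maximum")
        if self.distribution == "loguniform" and self.minimum <= 0:
            raise ValueError(f"{self.name}: loguniform requires minimum > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.distribution == "uniform":
            return float(rng.uniform(self.minimum, self.maximum))
        lo, hi = math.log(self.minimum), math.log(self.maximum)
        return float(math.exp(rng.uniform(lo, hi)))


def _prior_table() -> dict[str, PriorSpec]:
    rows = [
        ("N_cW", "loguniform", 10, 5_000),
        ("N_cE", "loguniform", 10, 5_000),
        ("N_mpW", "loguniform", 500, 50_000),
        ("N_mpE", "loguniform", 500, 50_000),
        ("N_lpW", "loguniform", 100, 50_000),
        ("N_lpE", "loguniform", 100, 50_000),
        ("N_hW", "loguniform", 500, 100_000),
        ("N_hE", "loguniform", 500, 100_000),
        ("N_s", "loguniform", 100, 50_000),
        ("N_gs1", "loguniform", 100, 50_000),
        ("N_gs2", "loguniform", 100, 50_000),
        ("P_lgm", "uniform", 0.0, 1.0),
        ("T_s1", "uniform", 14.7, 19.0),   # ka
        ("T_s2", "uniform", 28.0, 37.0),   # ka
        ("p_holo", "uniform", 0.0, 1.0),
        ("m_mp", "loguniform", 1e-6, 1e-3),
        ("m_lp", "loguniform", 1e-6, 1e-3),
        ("m_lg", "loguniform", 1e-6, 1e-3),
        # Per-generation phenotypic mutation rate shared by all traits.
        ("mu", "uniform", 2.6e-4, 5e-2),
    ]
    return {n: PriorSpec(n, d, float(lo), float(hi)) for n, d, lo, hi in rows}


_DEFAULT_PRIORS = _prior_table()


def default_priors() -> dict[str, PriorSpec]:
    """The default prior set (a fresh copy; edit freely)."""
    return dict(_DEFAULT_PRIORS)


def load_priors(path=None) -> dict[str, PriorSpec]:
    """Load priors from a YAML file; ``None`` loads the packaged defaults.

    The YAML schema is ``{name: {distribution, minimum, maximum}}``.
    """
    if path is None:
        text = resources.files("dentabc.data").joinpath("priors.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    priors = {}
    for name, spec in raw.items():
        priors[name] = PriorSpec(
            name=name,
            distribution=spec["distribution"],
            minimum=float(spec["minimum"]),
            maximum=float(spec["maximum"]),
        )
    return priors


def draw_parameters(
    priors: Mapping[str, PriorSpec],
    rng: np.random.Generator | int,
    overrides: Mapping[str, float | PriorSpec] | None = None,
) -> dict[str, float]:
    """Draw one value per prior; ``overrides`` pins values or swaps priors.

    Draws are made in sorted name order so the result is reproducible for
    a fixed seed regardless of the mapping's insertion order.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    overrides = dict(overrides or {})
    out: dict[str, float] = {}
    for name in sorted(priors):
        ov = overrides.get(name)
        if ov is None:
            out[name] = priors[name].sample(rng)
        elif isinstance(ov, PriorSpec):
            out[name] = ov.sample(rng)
        else:
            out[name] = float(ov)
    for name in overrides:
        if name not in priors:
            raise KeyError(f"override for unknown parameter {name!r}")
    return out


# ---------------------------------------------------------------------------
# Realized demography: concrete event schedule for one parameter draw.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeSegment:
    """Deme size over backward-time interval [t_lo, t_hi).

    ``N(t) = n_lo * exp(growth * (t - t_lo))`` with t in generations
    before present.
    """

    t_lo: float
    t_hi: float
    n_lo: float
    growth: float = 0.0

    def size_at(self, t: float) -> float:
        return self.n_lo * math.exp(self.growth * (t - self.t_lo))


@dataclass(frozen=True)
class Deme:
    name: str
    segments: tuple[SizeSegment, ...]  # contiguous, covering [0, inf)

    def __post_init__(self):
        starts = [s.t_lo for s in self.segments]
        if starts[0] != 0.0 or any(
            a.t_hi != b.t_lo for a, b in zip(self.segments, self.segments[1:])
        ):
            raise ValueError(f"deme {self.name}: segments must tile [0, inf)")
        object.__setattr__(self, "_starts", starts)

    def segment_at(self, t: float) -> SizeSegment:
        i = bisect_right(self._starts, t) - 1
        return self.segments[i]

    def size_at(self, t: float) -> float:
        return self.segment_at(t).size_at(t)


@dataclass(frozen=True)
class MigrationEpoch:
    """Directional per-lineage backward migration rates over [t_lo, t_hi)."""

    t_lo: float
    t_hi: float
    pairs: tuple[tuple[str, str, float], ...]  # (source, dest, rate/gen)


@dataclass(frozen=True)
class LineageMove:
    """At ``time``, each lineage in ``source`` moves to a destination.

    ``dests`` is a tuple of (deme, probability); probabilities sum to one.
    A single (deme, 1.0) entry encodes a full merge/replacement; two
    entries encode an admixture split (backward in time).
    """

    time: float
    source: str
    dests: tuple[tuple[str, float], ...]

    def __post_init__(self):
        total = sum(p for _, p in self.dests)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("destination probabilities must sum to 1")


@dataclass
class RealizedDemography:
    """A fully parameterized, simulable backward-time event schedule."""

    demes: dict[str, Deme]
    migrations: list[MigrationEpoch]
    moves: list[LineageMove]
    sample_demes: dict[tuple[str, str], str]  # (region, period) -> deme
    root: str = "anc"
    model_id: int | None = None

    def __post_init__(self):
        self.moves = sorted(self.moves, key=lambda m: m.time)
        self.validate()

    def validate(self) -> None:
        for deme in self.demes.values():
            for seg in deme.segments:
                if seg.n_lo <= 0:
                    raise ValueError(f"deme {deme.name}: non-positive size")
        for mv in self.moves:
            for dest, p in mv.dests:
                if dest not in self.demes:
                    raise ValueError(f"move destination {dest!r} unknown")
                if not 0.0 <= p <= 1.0:
                    raise ValueError("move probability outside [0, 1]")
            if mv.source not in self.demes:
                raise ValueError(f"move source {mv.source!r} unknown")
        for ep in self.migrations:
            if ep.t_lo >= ep.t_hi:
                raise ValueError("migration epoch must have t_lo < t_hi")
            for src, dst, rate in ep.pairs:
                if rate < 0:
                    raise ValueError("negative migration rate")
                if src not in self.demes or dst not in self.demes:
                    raise ValueError("migration between unknown demes")
        for grp, deme in self.sample_demes.items():
            if deme not in self.demes:
                raise ValueError(f"sample deme {deme!r} for group {grp} unknown")
        if self.root not in self.demes:
            raise ValueError("root deme missing")

    def terminal_demes(self) -> set[str]:
        """Demes whose lineages can still be somewhere at the final merge."""
        return {name for name in self.demes}


# -- trajectory archetypes (backward time) ----------------------------------


def _const(t_lo: float, t_hi: float, n: float) -> SizeSegment:
    return SizeSegment(t_lo, t_hi, n, 0.0)


def _grow(t_young: float, t_old: float, n_young: float, n_old: float) -> SizeSegment:
    """Exponential bridge: size n_young at t_young, n_old at t_old (backward)."""
    g = math.log(n_old / n_young) / (t_old - t_young)
    return SizeSegment(t_young, t_old, n_young, g)


def _traj_plain(n_c: float, n_h: float) -> tuple[SizeSegment, ...]:
    # Continuity without bottleneck: N_c at 47 ka -> N_h at 7 ka, then flat.
    return (_const(0, T7, n_h), _grow(T7, T47, n_h, n_c), _const(T47, _INF, n_c))


def _traj_bottleneck(n_c, n_mp, n_h, p_lgm) -> tuple[SizeSegment, ...]:
    # N_c at 47 -> N_mp at 26.5; p*N_mp during LGM; -> N_h at 7; flat after.
    nb = p_lgm * n_mp
    return (
        _const(0, T7, n_h),
        _grow(T7, T19, n_h, nb),
        _const(T19, T265, nb),
        _grow(T265, T47, n_mp, n_c),
        _const(T47, _INF, n_c),
    )


def _traj_doomed_147(n_c, n_mp, n_lp, p_lgm) -> tuple[SizeSegment, ...]:
    # Replaced at 14.7 ka with terminal size n_lp; earlier history as model 3.
    nb = p_lgm * n_mp
    return (
        _const(0, T147, n_lp),
        _grow(T147, T19, n_lp, nb),
        _const(T19, T265, nb),
        _grow(T265, T47, n_mp, n_c),
        _const(T47, _INF, n_c),
    )


def _traj_doomed_28(n_c, n_mp) -> tuple[SizeSegment, ...]:
    # Replaced at 28 ka with terminal size n_mp.
    return (_const(0, T28, n_mp), _grow(T28, T47, n_mp, n_c), _const(T47, _INF, n_c))


def _traj_incoming_147(n_h, n_s) -> tuple[SizeSegment, ...]:
    # Arrives at 14.7 ka with size n_s, grows to n_h at 7 ka; constant n_s
    # back to its divergence time.
    return (_const(0, T7, n_h), _grow(T7, T147, n_h, n_s), _const(T147, _INF, n_s))


def _traj_incoming_28(n_h, n_s, p_lgm) -> tuple[SizeSegment, ...]:
    # Arrives at 28 ka with size n_s; LGM bottleneck applies to n_s; grows to
    # n_h at 7 ka; constant n_s back to its divergence time.
    nb = p_lgm * n_s
    return (
        _const(0, T7, n_h),
        _grow(T7, T19, n_h, nb),
        _const(T19, T265, nb),
        _const(T265, _INF, n_s),
    )


def _traj_incoming_28_doomed_147(n_lp, n_s, p_lgm) -> tuple[SizeSegment, ...]:
    # Arrives at 28 ka with size n_s, bottlenecked to p*n_s, grows to n_lp at
    # 14.7 ka where it is itself replaced.
    nb = p_lgm * n_s
    return (
        _const(0, T147, n_lp),
        _grow(T147, T19, n_lp, nb),
        _const(T19, T265, nb),
        _const(T265, _INF, n_s),
    )


def _traj_ghost(n_g: float) -> tuple[SizeSegment, ...]:
    return (_const(0, _INF, n_g),)


# -- model assembly ----------------------------------------------------------

MODEL_CATEGORIES = {
    **{m: "Continuity" for m in (1, 2, 3)},
    **{m: "DiscontinuityWest" for m in (4, 5, 6, 7)},
    **{m: "DiscontinuityEast" for m in range(8, 15)},
}

#: Category structure used by the step-wise model-selection protocol.
DEFAULT_CATEGORIES = {
    "Continuity": (1, 2, 3),
    "DiscontinuityWest": (4, 5, 6, 7),
    "DiscontinuityEast": (8, 9, 10, 11, 12, 13, 14),
}

_PERIODS = ("MPG", "LPG", "LG&EH")


def _samples(w_map: Mapping[str, str], e_map: Mapping[str, str]):
    out = {}
    for p in _PERIODS:
        out[("West", p)] = w_map[p]
        out[("East", p)] = e_map[p]
    return out


def _mig(pairs_by_epoch: dict[tuple[float, float], list[tuple[str, str, float]]]):
    epochs = []
    for (lo, hi), pairs in pairs_by_epoch.items():
        sym = []
        for a, b, r in pairs:
            sym.append((a, b, r))
            sym.append((b, a, r))
        epochs.append(MigrationEpoch(lo, hi, tuple(sym)))
    return epochs


MPG_EPOCH = (T28, T47)
LPG_EPOCH = (T147, T28)
LGEH_EPOCH = (T7, T147)


def _realize(model_id: int, p: Mapping[str, float]) -> RealizedDemography:
    ts1 = ka_to_generations(p["T_s1"])
    ts2 = ka_to_generations(p["T_s2"])
    anc = Deme("anc", _traj_ghost(N_ANCESTRAL))
    demes: dict[str, Deme] = {"anc": anc}
    moves: list[LineageMove] = []
    mig: dict[tuple[float, float], list[tuple[str, str, float]]] = {}
    m = model_id

    def final_merges(*names: str) -> None:
        for n in names:
            moves.append(LineageMove(T47, n, ((("anc"), 1.0),)))

    if m in (1, 2, 3):
        if m == 3:
            w_traj = _traj_bottleneck(p["N_cW"], p["N_mpW"], p["N_hW"], p["P_lgm"])
            e_traj = _traj_bottleneck(p["N_cE"], p["N_mpE"], p["N_hE"], p["P_lgm"])
        else:
            w_traj = _traj_plain(p["N_cW"], p["N_hW"])
            e_traj = _traj_plain(p["N_cE"], p["N_hE"])
        demes["W"] = Deme("W", w_traj)
        demes["E"] = Deme("E", e_traj)
        final_merges("W", "E")
        mig[MPG_EPOCH] = [("W", "E", p["m_mp"])]
        if m == 1:
            mig[LPG_EPOCH] = [("W", "E", p["m_lp"])]
        mig[LGEH_EPOCH] = [("W", "E", p["m_lg"])]
        samples = _samples({q: "W" for q in _PERIODS}, {q: "E" for q in _PERIODS})

    elif m in (4, 5, 6, 7):
        demes["E"] = Deme("E", _traj_bottleneck(p["N_cE"], p["N_mpE"], p["N_hE"], p["P_lgm"]))
        if m == 4:
            demes["W_pre"] = Deme(
                "W_pre", _traj_doomed_147(p["N_cW"], p["N_mpW"], p["N_lpW"], p["P_lgm"])
            )
            demes["W"] = Deme("W", _traj_incoming_147(p["N_hW"], p["N_s"]))
            moves.append(LineageMove(ts1, "W", (("E", 1.0),)))
            final_merges("W_pre", "E")
            mig[MPG_EPOCH] = [("W_pre", "E", p["m_mp"])]
            samples = _samples({"MPG": "W_pre", "LPG": "W_pre", "LG&EH": "W"},
                               {q: "E" for q in _PERIODS})
        elif m == 5:
            demes["W_pre"] = Deme("W_pre", _traj_doomed_28(p["N_cW"], p["N_mpW"]))
            demes["W"] = Deme("W", _traj_incoming_28(p["N_hW"], p["N_s"], p["P_lgm"]))
            moves.append(LineageMove(ts2, "W", (("E", 1.0),)))
            final_merges("W_pre", "E")
            mig[MPG_EPOCH] = [("W_pre", "E", p["m_mp"])]
            mig[LGEH_EPOCH] = [("W", "E", p["m_lg"])]
            samples = _samples({"MPG": "W_pre", "LPG": "W", "LG&EH": "W"},
                               {q: "E" for q in _PERIODS})
        else:  # 6 and 7
            demes["W_mpg"] = Deme("W_mpg", _traj_doomed_28(p["N_cW"], p["N_mpW"]))
            demes["W_lpg"] = Deme(
                "W_lpg", _traj_incoming_28_doomed_147(p["N_lpW"], p["N_s"], p["P_lgm"])
            )
            demes["W"] = Deme("W", _traj_incoming_147(p["N_hW"], p["N_s"]))
            moves.append(LineageMove(ts1, "W", (("E", 1.0),)))
            moves.append(LineageMove(ts2, "W_lpg", (("E", 1.0),)))
            final_merges("W_mpg", "E")
            if m == 6:
                mig[MPG_EPOCH] = [("W_mpg", "E", p["m_mp"])]
            samples = _samples({"MPG": "W_mpg", "LPG": "W_lpg", "LG&EH": "W"},
                               {q: "E" for q in _PERIODS})

    elif m in range(8, 15):
        demes["W"] = Deme("W", _traj_bottleneck(p["N_cW"], p["N_mpW"], p["N_hW"], p["P_lgm"]))
        if m in (8, 9, 10):
            demes["E_pre"] = Deme(
                "E_pre", _traj_doomed_147(p["N_cE"], p["N_mpE"], p["N_lpE"], p["P_lgm"])
            )
            demes["E"] = Deme("E", _traj_incoming_147(p["N_hE"], p["N_s"]))
            final_merges("E_pre", "W")
            if m == 8:
                moves.append(LineageMove(ts1, "E", (("W", 1.0),)))
            else:
                demes["ghost1"] = Deme("ghost1", _traj_ghost(p["N_gs1"]))
                final_merges("ghost1")
                if m == 9:
                    moves.append(LineageMove(ts1, "E", (("ghost1", 1.0),)))
                else:  # 10: admixed incoming, fraction p_holo from the West
                    moves.append(
                        LineageMove(
                            ts1, "E",
                            (("W", p["p_holo"]), ("ghost1", 1.0 - p["p_holo"])),
                        )
                    )
            mig[MPG_EPOCH] = [("W", "E_pre", p["m_mp"])]
            samples = _samples({q: "W" for q in _PERIODS},
                               {"MPG": "E_pre", "LPG": "E_pre", "LG&EH": "E"})
        elif m == 11:
            demes["E_pre"] = Deme("E_pre", _traj_doomed_28(p["N_cE"], p["N_mpE"]))
            demes["E"] = Deme("E", _traj_incoming_28(p["N_hE"], p["N_s"], p["P_lgm"]))
            demes["ghost1"] = Deme("ghost1", _traj_ghost(p["N_gs1"]))
            moves.append(LineageMove(ts2, "E", (("ghost1", 1.0),)))
            final_merges("E_pre", "W", "ghost1")
            mig[MPG_EPOCH] = [("W", "E_pre", p["m_mp"])]
            mig[LGEH_EPOCH] = [("W", "E", p["m_lg"])]
            samples = _samples({q: "W" for q in _PERIODS},
                               {"MPG": "E_pre", "LPG": "E", "LG&EH": "E"})
        else:  # 12, 13, 14
            demes["E_mpg"] = Deme("E_mpg", _traj_doomed_28(p["N_cE"], p["N_mpE"]))
            demes["E_lpg"] = Deme(
                "E_lpg", _traj_incoming_28_doomed_147(p["N_lpE"], p["N_s"], p["P_lgm"])
            )
            demes["E"] = Deme("E", _traj_incoming_147(p["N_hE"], p["N_s"]))
            demes["ghost1"] = Deme("ghost1", _traj_ghost(p["N_gs1"]))
            demes["ghost2"] = Deme("ghost2", _traj_ghost(p["N_gs2"]))
            if m == 12:
                moves.append(LineageMove(ts1, "E", (("ghost1", 1.0),)))
            else:  # 13, 14: admixed LG&EH incoming (ghost1 / West)
                moves.append(
                    LineageMove(
                        ts1, "E",
                        (("W", p["p_holo"]), ("ghost1", 1.0 - p["p_holo"])),
                    )
                )
            moves.append(LineageMove(ts2, "E_lpg", (("ghost2", 1.0),)))
            final_merges("E_mpg", "W", "ghost1", "ghost2")
            if m != 14:
                mig[MPG_EPOCH] = [("W", "E_mpg", p["m_mp"])]
            samples = _samples({q: "W" for q in _PERIODS},
                               {"MPG": "E_mpg", "LPG": "E_lpg", "LG&EH": "E"})
    else:
        raise ValueError(f"model_id must be in 1..14, got {model_id}")

    return RealizedDemography(
        demes=demes,
        migrations=_mig(mig),
        moves=moves,
        sample_demes=samples,
        root="anc",
        model_id=model_id,
    )


@dataclass(frozen=True)
class DemographicModel:
    """One of the 14 demographic scenarios; call :meth:`realize` with a
    parameter draw to obtain a simulable event schedule."""

    model_id: int
    category: str = field(compare=False)

    def realize(self, params: Mapping[str, float]) -> RealizedDemography:
        return _realize(self.model_id, params)


def build_model(model_id: int) -> DemographicModel:
    """Return the scenario with the given id (1-14)."""
    if model_id not in MODEL_CATEGORIES:
        raise ValueError(f"model_id must be in 1..14, got {model_id}")
    return DemographicModel(model_id=model_id, category=MODEL_CATEGORIES[model_id])


def all_models() -> list[DemographicModel]:
    return [build_model(i) for i in range(1, 15)]
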