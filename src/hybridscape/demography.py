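"""Demographic scenarios compiled to piecewise-constant structured-coalescent schedules.

Units follow the diffusion-approximation conventions common in joint-SFS
inference: population sizes are relative to an ancestral reference N_ref
(the ancestral population has size 1), times are in units of 2*N_ref
generations, and migration rates are scaled as M = 2*N_ref*m with M12 the
donor->recipient rate from population 1 into population 2 *forward* in time.
Backward in time a lineage currently in population 2 therefore jumps to
population 1 at rate M12/2 per unit time.

Two-population model space
    SI, IM, AM, SC             -- divergence with no / continuous / ancient /
                                  secondary-contact gene flow
    +G (SIG, IMG, ...)         -- exponential size change over the terminal
                                  epoch, from the ancestral size to nu_i
    +2m (IM2m, ...)            -- two locus classes sharing all parameters
                                  except migration (me12/me21 for a fraction
                                  P of loci), plus an orientation parameter O
Three-population model space (parent 1, parent 2, hybrid)
    HS                         -- hybrid founded at Th by a punctual admixture
                                  pulse (fraction f from parent 1), no later
                                  gene flow
    HSp1 / HSp2 / HS2p         -- HS plus gene flow between the hybrid and
                                  parent 1 / parent 2 / both
    SGF1 / SGF2                -- hybrid splits from parent 1 / parent 2 at
                                  Th, then exchanges genes with both parents
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScenarioParams",
    "Event",
    "EventSchedule",
    "CompiledScenario",
    "ParameterMismatchError",
    "ChronologyError",
    "TWO_POP_MODELS",
    "THREE_POP_MODELS",
    "MODEL_PARAMS",
    "PARAM_KINDS",
    "free_params",
    "compile_scenario",
    "compile_two_pop",
    "compile_three_pop",
]

_BIG = 1e30
_GROWTH_SLICES = 16


class ParameterMismatchError(ValueError):
    """Supplied parameters do not match what the named model needs."""


class ChronologyError(ValueError):
    """Event times are not consistently ordered."""


@dataclass
class ScenarioParams:
    """Named demographic parameters; unused fields stay ``None``.

    nu1/nu2/nu3: deme sizes relative to N_ref.  M12/M21 (and m13/m31/m23/m32
    for triplets): scaled migration 2*N_ref*m, donor->recipient forward in
    time.  me12/me21: reduced rates for the restricted locus class, a
    fraction P of the genome.  O: probability a site's ancestral/derived
    orientation is correct.  Ts: parental split time; Tam: duration of the
    ancient-migration phase (adjacent to the split); Tsc: duration of the
    secondary-contact phase (adjacent to the present); Th: hybrid-lineage
    origin time; f: ancestry fraction from parent 1 at the hybrid origin.
    theta: 4*N_ref*mu*L, free scaling never needed for compilation.
    """

    nu1: float | None = None
    nu2: float | None = None
    nu3: float | None = None
    M12: float | None = None
    M21: float | None = None
    m13: float | None = None
    m31: float | None = None
    m23: float | None = None
    m32: float | None = None
    me12: float | None = None
    me21: float | None = None
    P: float | None = None
    O: float | None = None
    Ts: float | None = None
    Tam: float | None = None
    Tsc: float | None = None
    Th: float | None = None
    f: float | None = None
    theta: float | None = None

    def set_fields(self) -> set[str]:
        return {
            f.name
            for f in dataclasses.fields(self)
            if f.name != "theta" and getattr(self, f.name) is not None
        }


@dataclass
class Event:
    """Discrete lineage movement at an epoch boundary (backward in time).

    kind "move": every lineage in deme ``a`` relocates to deme ``b``
    (a population split, seen backward).  kind "admix": every lineage in
    deme ``a`` independently relocates to ``b`` with probability ``prob``,
    else to ``c`` (a punctual admixture pulse).
    """

    time: float
    kind: str
    a: int
    b: int
    c: int = -1
    prob: float = 1.0


@dataclass
class EventSchedule:
    """Ordered epochs (backward in time) with sizes, migration, and events.

    ``epoch_times`` has one more entry than epochs; the last entry is
    effectively infinite.  ``mig[e, d, b]`` is the *backward* per-lineage
    rate at which a lineage in deme ``d`` jumps to deme ``b`` during epoch
    ``e``.  Events fire on entry to the epoch starting at their time.
    """

    n_demes: int
    epoch_times: np.ndarray
    sizes: np.ndarray
    mig: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.mig = np.asarray(self.mig, dtype=float)
        ne = len(self.epoch_times) - 1
        if self.sizes.shape != (ne, self.n_demes):
            raise ValueError("sizes shape mismatch")
        if self.mig.shape != (ne, self.n_demes, self.n_demes):
            raise ValueError("mig shape mismatch")
        if np.diff(self.epoch_times).min() <= 0:
            raise ChronologyError("epoch durations must be positive")
        if (self.sizes <= 0).any():
            raise ValueError("deme sizes must be positive")
        if (self.mig < 0).any() or np.abs(np.einsum("edd->ed", self.mig)).max() > 0:
            raise ValueError("migration matrices must be non-negative with zero diagonal")
        self._check_single_root()

    def _check_single_root(self) -> None:
        active = set(range(self.n_demes))
        for ev in sorted(self.events, key=lambda e: e.time):
            if ev.kind == "move":
                active.discard(ev.a)
                active.add(ev.b)
            elif ev.kind == "admix":
                active.discard(ev.a)
                active.update((ev.b, ev.c))
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
        if len(active) != 1:
            raise ValueError(f"schedule must end with exactly one root deme, got {active}")

    def event_epochs(self) -> np.ndarray:
        """Index of the epoch each event fires on entry to."""
        out = []
        for ev in self.events:
            idx = np.flatnonzero(np.isclose(self.epoch_times[:-1], ev.time))
            if idx.size != 1:
                raise ChronologyError(f"event at t={ev.time} is not on an epoch boundary")
            out.append(int(idx[0]))
        return np.asarray(out, dtype=np.int64)


@dataclass
class CompiledScenario:
    """Weighted locus-class schedules plus the orientation parameter."""

    model: str
    schedules: list[tuple[EventSchedule, float]]
    O: float | None = None
    n_pops: int = 2


# ---------------------------------------------------------------------------
# Model registry

_TWO_BASE = ("nu1", "nu2", "Ts")
_MIG = ("M12", "M21")
_2M = ("me12", "me21", "P", "O")

TWO_POP_MODELS: dict[str, tuple[str, ...]] = {}
for _phase, _extra in (("SI", ()), ("IM", _MIG), ("AM", _MIG + ("Tam",)), ("SC", _MIG + ("Tsc",))):
    TWO_POP_MODELS[_phase] = _TWO_BASE + _extra
    TWO_POP_MODELS[_phase + "G"] = _TWO_BASE + _extra
    if _phase != "SI":
        TWO_POP_MODELS[_phase + "2m"] = _TWO_BASE + _extra + _2M
        TWO_POP_MODELS[_phase + "2mG"] = _TWO_BASE + _extra + _2M

_THREE_BASE = ("nu1", "nu2", "nu3", "Ts", "Th")
THREE_POP_MODELS: dict[str, tuple[str, ...]] = {
    "HS": _THREE_BASE + ("f",),
    "HSp1": _THREE_BASE + ("f", "m13", "m31"),
    "HSp2": _THREE_BASE + ("f", "m23", "m32"),
    "HS2p": _THREE_BASE + ("f", "m13", "m31", "m23", "m32"),
    "SGF1": _THREE_BASE + ("m13", "m31", "m23", "m32"),
    "SGF2": _THREE_BASE + ("m13", "m31", "m23", "m32"),
}

MODEL_PARAMS: dict[str, tuple[str, ...]] = {**TWO_POP_MODELS, **THREE_POP_MODELS}

#: how each parameter is transformed during optimization
PARAM_KINDS: dict[str, str] = {
    "nu1": "size", "nu2": "size", "nu3": "size",
    "M12": "mig", "M21": "mig", "m13": "mig", "m31": "mig",
    "m23": "mig", "m32": "mig", "me12": "mig", "me21": "mig",
    "Ts": "time", "Th": "timefrac", "Tam": "timefrac", "Tsc": "timefrac",
    "P": "frac", "O": "frac", "f": "frac",
}


def free_params(model: str) -> tuple[str, ...]:
    """Names of the model's free parameters (theta excluded: it is profiled
    analytically in the composite likelihood)."""
    try:
        return MODEL_PARAMS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None


def _validate(model: str, p: ScenarioParams) -> None:
    need = set(free_params(model))
    have = p.set_fields()
    missing, extra = need - have, have - need
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing {sorted(missing)}")
        if extra:
            parts.append(f"extraneous {sorted(extra)}")
        raise ParameterMismatchError(f"model {model}: " + "; ".join(parts))
    for name in ("f", "P", "O"):
        v = getattr(p, name)
        if v is not None and not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    for name in ("nu1", "nu2", "nu3", "Ts"):
        v = getattr(p, name)
        if v is not None and v <= 0:
            raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Two-population compilation


def _growth_slices(t0: float, t1: float, Ts: float) -> np.ndarray:
    n = max(1, int(round(_GROWTH_SLICES * (t1 - t0) / Ts)))
    return np.linspace(t0, t1, n + 1)


def _two_pop_schedule(
    nu: tuple[float, float],
    Ts: float,
    mig_windows: list[tuple[float, float, float, float]],
    growth: bool,
) -> EventSchedule:
    """Assemble one 2-deme schedule.  *mig_windows* is a list of
    (start, end, M12, M21) with 0 <= start < end <= Ts; outside every window
    migration is zero."""
    bounds = {0.0, Ts}
    for a, b, *_ in mig_windows:
        bounds.update((a, b))
    bounds = sorted(bounds)
    times, sizes, migs = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        M12 = M21 = 0.0
        for wa, wb, w12, w21 in mig_windows:
            if a >= wa - 1e-12 and b <= wb + 1e-12:
                M12, M21 = w12, w21
        mmat = np.array([[0.0, M21 / 2.0], [M12 / 2.0, 0.0]])
        if growth:
            cuts = _growth_slices(a, b, Ts)
            for c0, c1 in zip(cuts[:-1], cuts[1:]):
                tm = 0.5 * (c0 + c1)
                # exponential from the ancestral size (1) at Ts to nu_i now
                sz = [nu[0] ** (1.0 - tm / Ts), nu[1] ** (1.0 - tm / Ts)]
                times.append(c0)
                sizes.append(sz)
                migs.append(mmat)
        else:
            times.append(a)
            sizes.append(list(nu))
            migs.append(mmat)
    times.append(Ts)
    sizes.append([1.0, 1.0])
    migs.append(np.zeros((2, 2)))
    times.append(_BIG)
    events = [Event(Ts, "move", a=1, b=0)]
    return EventSchedule(2, np.array(times), np.array(sizes), np.stack(migs), events)


def compile_two_pop(model: str, p: ScenarioParams) -> CompiledScenario:
    """Compile a named two-population divergence model into weighted
    locus-class schedules (two classes for 2m models, one otherwise)."""
    if model not in TWO_POP_MODELS:
        raise ValueError(f"unknown two-population model {model!r}")
    _validate(model, p)
    growth = model.endswith("G")
    base = model[:-1] if growth else model
    two_m = base.endswith("2m")
    phase = base[:-2] if two_m else base
    nu, Ts = (p.nu1, p.nu2), p.Ts

    def windows(M12: float, M21: float) -> list:
        if phase == "SI":
            return []
        if phase == "IM":
            return [(0.0, Ts, M12, M21)]
        if phase == "AM":
            if not 0 < p.Tam < Ts:
                raise ChronologyError("AM requires 0 < Tam < Ts")
            return [(Ts - p.Tam, Ts, M12, M21)]
        if phase == "SC":
            if not 0 < p.Tsc < Ts:
                raise ChronologyError("SC requires 0 < Tsc < Ts")
            return [(0.0, p.Tsc, M12, M21)]
        raise AssertionError(phase)

    if phase == "SI":
        sched = _two_pop_schedule(nu, Ts, [], growth)
        return CompiledScenario(model, [(sched, 1.0)], O=p.O, n_pops=2)
    neutral = _two_pop_schedule(nu, Ts, windows(p.M12, p.M21), growth)
    if not two_m:
        return CompiledScenario(model, [(neutral, 1.0)], O=p.O, n_pops=2)
    restricted = _two_pop_schedule(nu, Ts, windows(p.me12, p.me21), growth)
    return CompiledScenario(
        model, [(neutral, 1.0 - p.P), (restricted, p.P)], O=p.O, n_pops=2
    )


# ---------------------------------------------------------------------------
# Three-population compilation


def compile_three_pop(model: str, p: ScenarioParams) -> CompiledScenario:
    """Compile a hybrid-speciation (HS*) or secondary-gene-flow (SGF*) model.

    Demes: 0 = parent 1, 1 = parent 2, 2 = hybrid lineage.  Gene flow in
    these models involves only the hybrid deme; the parents do not exchange
    genes directly.
    """
    if model not in THREE_POP_MODELS:
        raise ValueError(f"unknown three-population model {model!r}")
    _validate(model, p)
    if p.Th >= p.Ts:
        raise ChronologyError(f"hybrid origin Th={p.Th} must predate the split Ts={p.Ts}")
    m13 = p.m13 or 0.0
    m31 = p.m31 or 0.0
    m23 = p.m23 or 0.0
    m32 = p.m32 or 0.0
    # backward per-lineage rates: recipient deme traces to donor at M/2
    mig0 = np.zeros((3, 3))
    mig0[2, 0] = m13 / 2.0  # hybrid ancestry from parent 1
    mig0[0, 2] = m31 / 2.0
    mig0[2, 1] = m23 / 2.0
    mig0[1, 2] = m32 / 2.0
    times = [0.0, p.Th, p.Ts, _BIG]
    sizes = np.array(
        [
            [p.nu1, p.nu2, p.nu3],
            [p.nu1, p.nu2, 1.0],  # hybrid deme empty after Th (backward)
            [1.0, 1.0, 1.0],
        ]
    )
    migs = np.stack([mig0, np.zeros((3, 3)), np.zeros((3, 3))])
    if model.startswith("HS"):
        origin = Event(p.Th, "admix", a=2, b=0, c=1, prob=p.f)
    elif model == "SGF1":
        origin = Event(p.Th, "move", a=2, b=0)
    else:  # SGF2
        origin = Event(p.Th, "move", a=2, b=1)
    events = [origin, Event(p.Ts, "move", a=1, b=0)]
    sched = EventSchedule(3, np.array(times), sizes, migs, events)
    return CompiledScenario(model, [(sched, 1.0)], O=None, n_pops=3)


def compile_scenario(model: str, p: ScenarioParams) -> CompiledScenario:
    """Dispatch to the two- or three-population compiler by model name."""
    if model in TWO_POP_MODELS:
        return compile_two_pop(model, p)
    if model in THREE_POP_MODELS:
        return compile_three_pop(model, p)
    raise ValueError(f"unknown model {model!r}")
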