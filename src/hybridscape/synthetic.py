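"""Synthetic data with known truth for every pipeline stage.

Three generators cover the pipeline's inputs:

* :func:`gen_species_complex` -- diploid SNP genotypes for 2-4 taxa under a
  compiled demographic scenario.  Each locus gets one simulated genealogy
  (a pure-Python structured coalescent that tracks leaf identity, distinct
  from the branch-length engine used for inference) and at most one
  infinite-sites mutation placed proportionally to branch length.
* :func:`gen_contact_zone` -- contact-zone individuals of known ancestry
  class (pure parentals, F1, F2, backcrosses) drawn from parental allele
  frequencies by explicit gamete formation, loci unlinked.
* :func:`gen_occurrences` -- Gaussian climatic niches in the 5-variable
  bioclim space.

Every generator is deterministic given (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import CompiledScenario, EventSchedule, Event, ScenarioParams, compile_scenario
from .genotypes import MISSING, GenotypeMatrix
from .niche import CLIMATE_VARIABLES

__all__ = [
    "TruthRecord",
    "gen_species_complex",
    "gen_contact_zone",
    "gen_occurrences",
    "four_taxon_complex",
    "diagnostic_freqs",
    "CLASS_TRUE_H",
]

#: true hybrid index (ancestry share from parent B) per contact-zone class
CLASS_TRUE_H = {"pureA": 0.0, "pureB": 1.0, "F1": 0.5, "F2": 0.5, "BC1": 0.25, "BC2": 0.75}


@dataclass
class TruthRecord:
    """Ground truth accompanying a generated dataset."""

    scenario: str
    params: ScenarioParams | None
    ancestry_class: list[str]
    true_h: list[float]
    locus_class: np.ndarray | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-locus genealogy simulation (leaf-tracking, any number of demes)


def _simulate_locus(sched: EventSchedule, n_per_deme, rng: np.random.Generator):
    """One genealogy; returns (segments, total_length) where each segment is
    (leaf-bitmask, length)."""
    ntot = int(sum(n_per_deme))
    deme = []
    mask = []
    for d, n in enumerate(n_per_deme):
        for i in range(n):
            deme.append(d)
            mask.append(1 << len(mask))
    ev_epoch = sched.event_epochs()
    segments: list[tuple[int, float]] = []
    total = 0.0
    alive = ntot
    ne = sched.sizes.shape[0]
    full = (1 << ntot) - 1
    for e in range(ne):
        for v, ep in enumerate(ev_epoch):
            if ep == e:
                ev = sched.events[v]
                for i in range(alive):
                    if deme[i] == ev.a:
                        if ev.kind == "move" or ev.prob >= 1.0:
                            deme[i] = ev.b
                        elif ev.prob <= 0.0 or rng.random() >= ev.prob:
                            deme[i] = ev.c
                        else:
                            deme[i] = ev.b
        if alive <= 1:
            break
        t, t_end = sched.epoch_times[e], sched.epoch_times[e + 1]
        while alive > 1:
            kd = np.zeros(sched.n_demes, dtype=int)
            for i in range(alive):
                kd[deme[i]] += 1
            crate = 0.5 * kd * (kd - 1) / sched.sizes[e]
            mout = sched.mig[e].sum(axis=1)
            mrate = kd * mout
            tot = crate.sum() + mrate.sum()
            if tot <= 0:
                if t_end >= 1e29:
                    raise RuntimeError("no common root reachable")
                dt = t_end - t
            else:
                dt = rng.exponential(1.0 / tot)
                if t + dt >= t_end:
                    dt = t_end - t
            for i in range(alive):
                if mask[i] != full:
                    segments.append((mask[i], dt))
                    total += dt
            t += dt
            if tot <= 0 or t >= t_end - 1e-30:
                break
            r = rng.random() * tot
            acc = 0.0
            handled = False
            for d in range(sched.n_demes):
                acc += crate[d]
                if r < acc:
                    members = [i for i in range(alive) if deme[i] == d]
                    ii, jj = rng.choice(len(members), size=2, replace=False)
                    a, b = members[ii], members[jj]
                    mask[a] |= mask[b]
                    deme[b] = deme[alive - 1]
                    mask[b] = mask[alive - 1]
                    alive -= 1
                    handled = True
                    break
                acc += mrate[d]
                if r < acc:
                    members = [i for i in range(alive) if deme[i] == d]
                    ii = members[int(rng.random() * len(members))]
                    r2 = rng.random() * mout[d]
                    acc2 = 0.0
                    for bdeme in range(sched.n_demes):
                        acc2 += sched.mig[e, d, bdeme]
                        if r2 < acc2:
                            deme[ii] = bdeme
                            break
                    handled = True
                    break
            assert handled
        if alive <= 1:
            break
    return segments, total


def _place_mutation(segments, total, rng) -> int:
    u = rng.random() * total
    acc = 0.0
    for m, ln in segments:
        acc += ln
        if u < acc:
            return m
    return segments[-1][0]


def gen_species_complex(
    scenario,
    n_ind=15,
    n_loci: int = 1000,
    missing_rate: float = 0.0,
    seed: int = 0,
    theta_locus: float | None = None,
    species_names: list[str] | None = None,
    params: ScenarioParams | None = None,
):
    """Generate a diploid genotype matrix plus truth under a scenario.

    *scenario* is a model name (with *params*), a :class:`CompiledScenario`,
    or a bare :class:`EventSchedule`.  ``n_ind`` is the number of diploid
    individuals per sampled deme (an int or a list).  With ``theta_locus``
    set, each locus segregates with probability 1-exp(-theta*T/2) and
    monomorphic loci are emitted; by default every locus carries exactly one
    mutation placed proportionally to branch length (a SNP matrix).
    """
    name = scenario if isinstance(scenario, str) else getattr(scenario, "model", "custom")
    if isinstance(scenario, str):
        comp = compile_scenario(scenario, params)
    elif isinstance(scenario, EventSchedule):
        comp = CompiledScenario("custom", [(scenario, 1.0)], None, scenario.n_demes)
    else:
        comp = scenario
    n_demes_sampled = comp.n_pops
    if np.isscalar(n_ind):
        n_ind = [int(n_ind)] * n_demes_sampled
    n_per_deme = [2 * n for n in n_ind]
    ntot_hap = sum(n_per_deme)
    rng = np.random.default_rng(seed)
    weights = np.array([w for _, w in comp.schedules])
    weights = weights / weights.sum()
    locus_class = rng.choice(len(weights), size=n_loci, p=weights)
    haplo = np.zeros((ntot_hap, n_loci), dtype=np.int8)
    segregating = np.zeros(n_loci, dtype=bool)
    for j in range(n_loci):
        sched = comp.schedules[locus_class[j]][0]
        segments, total = _simulate_locus(sched, n_per_deme, rng)
        if theta_locus is not None and rng.random() > -np.expm1(-theta_locus * total / 2.0):
            continue
        m = _place_mutation(segments, total, rng)
        segregating[j] = True
        for h in range(ntot_hap):
            if m >> h & 1:
                haplo[h, j] = 1
    # misorientation: flip ref/alt with probability 1-O
    if comp.O is not None and comp.O < 1.0:
        flip = rng.random(n_loci) > comp.O
        haplo[:, flip & segregating] = 1 - haplo[:, flip & segregating]
    geno = haplo[0::2] + haplo[1::2]
    if species_names is None:
        species_names = [f"sp{d + 1}" for d in range(n_demes_sampled)]
    species = []
    ids = []
    for d, n in enumerate(n_ind):
        for i in range(n):
            species.append(species_names[d])
            ids.append(f"{species_names[d]}_{i}")
    if missing_rate > 0:
        miss = rng.random(geno.shape) < missing_rate
        geno[miss] = MISSING
    locus_ids = [f"L{j}" for j in range(n_loci)]
    gm = GenotypeMatrix(
        geno,
        ids,
        species,
        locus_ids,
        tag_ids=[f"tag{j}" for j in range(n_loci)],
    )
    truth = TruthRecord(
        scenario=name,
        params=params,
        ancestry_class=list(species),
        true_h=[float("nan")] * len(species),
        locus_class=locus_class,
        seed=seed,
        extra={"segregating": segregating},
    )
    return gm, truth


def four_taxon_complex(
    nu: float = 1.0,
    M: float = 2.0,
    me: float = 0.2,
    P: float = 0.3,
    Ts: float = 2.0,
    Th: float = 0.5,
    T_split_hybrids: float = 0.15,
    f: float = 0.5,
) -> CompiledScenario:
    """Default four-taxon study design: two parentals diverging with
    heterogeneous gene flow, a hybrid lineage founded at Th with ancestry
    fraction *f* from parent 1, splitting into two daughter taxa at
    *T_split_hybrids*.  Demes: 0 parent A, 1 parent B, 2 and 3 the two
    hybrid-origin taxa."""
    if not (0 < T_split_hybrids < Th < Ts):
        raise ValueError("require 0 < T_split_hybrids < Th < Ts")

    def sched(m12: float, m21: float) -> EventSchedule:
        times = np.array([0.0, T_split_hybrids, Th, Ts, 1e30])
        sizes = np.full((4, 4), nu)
        sizes[3, :] = 1.0  # ancestral population at the reference size
        mig = np.zeros((4, 4, 4))
        for e in (0, 1):  # parental gene flow until the split
            mig[e, 1, 0] = m12 / 2.0
            mig[e, 0, 1] = m21 / 2.0
        events = [
            Event(T_split_hybrids, "move", a=3, b=2),
            Event(Th, "admix", a=2, b=0, c=1, prob=f),
            Event(Ts, "move", a=1, b=0),
        ]
        return EventSchedule(4, times, sizes, mig, events)

    return CompiledScenario(
        "four_taxon_complex",
        [(sched(M, M), 1.0 - P), (sched(me, me), P)],
        O=None,
        n_pops=4,
    )


# ---------------------------------------------------------------------------
# Contact zones


def diagnostic_freqs(n_loci: int):
    """Fully diagnostic parental frequencies (pA=0, pB=1 at every locus)."""
    return np.zeros(n_loci), np.ones(n_loci)


def gen_contact_zone(
    freqsA,
    freqsB,
    class_counts: dict[str, int],
    seed: int = 0,
    missing_rate: float = 0.0,
):
    """Generate contact-zone individuals of known ancestry classes.

    Pure individuals are drawn under Hardy-Weinberg from one parental
    frequency set; an F1 receives one gamete from each parental pool; an F2
    two gametes from the F1 gamete pool; BC1/BC2 one parental (A/B) plus one
    F1 gamete.  Loci are unlinked, so an F1 gamete picks its parental origin
    independently per locus.
    """
    pA = np.asarray(freqsA["freq"] if isinstance(freqsA, pd.DataFrame) else freqsA, dtype=float)
    pB = np.asarray(freqsB["freq"] if isinstance(freqsB, pd.DataFrame) else freqsB, dtype=float)
    if pA.shape != pB.shape:
        raise ValueError("parental frequency tables differ in length")
    unknown = set(class_counts) - set(CLASS_TRUE_H)
    if unknown:
        raise ValueError(f"unknown ancestry classes {sorted(unknown)}")
    n_total = sum(class_counts.values())
    if n_total == 0:
        raise ValueError("zero individuals requested")
    rng = np.random.default_rng(seed)
    L = pA.size

    def gam_A():
        return (rng.random(L) < pA).astype(np.int8)

    def gam_B():
        return (rng.random(L) < pB).astype(np.int8)

    def gam_F1():
        # one gamete from an F1: per locus, the A- or B-derived copy
        a, b = gam_A(), gam_B()
        pick = rng.random(L) < 0.5
        return np.where(pick, a, b).astype(np.int8)

    makers = {
        "pureA": lambda: gam_A() + gam_A(),
        "pureB": lambda: gam_B() + gam_B(),
        "F1": lambda: gam_A() + gam_B(),
        "F2": lambda: gam_F1() + gam_F1(),
        "BC1": lambda: gam_A() + gam_F1(),
        "BC2": lambda: gam_B() + gam_F1(),
    }
    rows, ids, classes = [], [], []
    for cls in sorted(class_counts):
        for i in range(class_counts[cls]):
            rows.append(makers[cls]())
            ids.append(f"{cls}_{i}")
            classes.append(cls)
    geno = np.vstack(rows).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING
    gm = GenotypeMatrix(
        geno,
        ids,
        ["hybridzone"] * n_total,
        [f"L{j}" for j in range(L)],
        locality=["zone"] * n_total,
    )
    truth = TruthRecord(
        scenario="contact_zone",
        params=None,
        ancestry_class=classes,
        true_h=[CLASS_TRUE_H[c] for c in classes],
        seed=seed,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Occurrences


def gen_occurrences(
    n_per_species: dict[str, int],
    centers: dict[str, np.ndarray],
    spreads: dict[str, np.ndarray] | float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian niches in the 5-variable bioclim space."""
    rng = np.random.default_rng(seed)
    frames = []
    for sp in sorted(n_per_species):
        n = n_per_species[sp]
        mu = np.asarray(centers[sp], dtype=float)
        if mu.shape != (5,):
            raise ValueError("niche centers must be 5-vectors")
        sd = spreads[sp] if isinstance(spreads, dict) else spreads
        sd = np.broadcast_to(np.asarray(sd, dtype=float), (5,))
        if (sd <= 0).any():
            raise ValueError("spreads must be positive")
        X = rng.normal(mu, sd, size=(n, 5))
        df = pd.DataFrame(X, columns=list(CLIMATE_VARIABLES))
        df.insert(0, "species", sp)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
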