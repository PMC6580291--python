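"""Monte-Carlo expected joint SFS by structured-coalescent branch-length averaging.

For each replicate a genealogy of the sampled lineages is simulated under the
compiled schedule (pair coalescence rate 1/nu per unit time, per-lineage
migration rate M/2, time in units of 2*N_ref generations).  Every branch
contributes its length to the spectrum cell indexed by its descendant-leaf
counts per population; averaging over replicates and dividing by two yields
the expected spectrum per unit theta (for a single constant-size population
this is the classical theta/i law).  Branch-length weighting uses every
simulated genealogy fully, unlike Poisson mutation sampling.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .demography import CompiledScenario, EventSchedule
from .sfs import JointSFS, misorient_jafs

__all__ = ["expected_jafs"]


@njit(cache=True)
def _sim_reps(
    seeds,
    n_per_deme,
    epoch_times,
    sizes,
    mig,
    ev_epoch,
    ev_kind,  # 0 = move, 1 = admix
    ev_a,
    ev_b,
    ev_c,
    ev_p,
    strides,
    out,
):
    n_demes = sizes.shape[1]
    ne = sizes.shape[0]
    ntot = 0
    for d in range(n_per_deme.shape[0]):
        ntot += n_per_deme[d]
    deme = np.empty(ntot, dtype=np.int64)
    cnt = np.zeros((ntot, 3), dtype=np.int64)
    fidx = np.empty(ntot, dtype=np.int64)
    born = np.empty(ntot, dtype=np.float64)
    kd = np.empty(n_demes, dtype=np.int64)
    crate = np.empty(n_demes, dtype=np.float64)
    mrate = np.empty(n_demes, dtype=np.float64)
    mout = np.empty(n_demes, dtype=np.float64)

    for rep in range(seeds.shape[0]):
        np.random.seed(seeds[rep])
        # initialise one lineage per sampled chromosome
        i = 0
        for d in range(n_per_deme.shape[0]):
            for _ in range(n_per_deme[d]):
                deme[i] = d
                cnt[i, 0] = 0
                cnt[i, 1] = 0
                cnt[i, 2] = 0
                cnt[i, d] = 1
                fidx[i] = strides[d]
                born[i] = 0.0
                i += 1
        alive = ntot
        t = 0.0
        # branch lengths are accumulated lazily: a lineage's leaf counts only
        # change at coalescence, so its segment [born, t] is flushed to the
        # spectrum only then (migration just relabels the deme)
        for e in range(ne):
            # events scheduled on entry to this epoch
            for v in range(ev_epoch.shape[0]):
                if ev_epoch[v] == e:
                    if ev_kind[v] == 0:
                        for i in range(alive):
                            if deme[i] == ev_a[v]:
                                deme[i] = ev_b[v]
                    else:
                        for i in range(alive):
                            if deme[i] == ev_a[v]:
                                # degenerate pulses stay deterministic so the
                                # nested-model limits are bit-identical
                                if ev_p[v] >= 1.0:
                                    deme[i] = ev_b[v]
                                elif ev_p[v] <= 0.0:
                                    deme[i] = ev_c[v]
                                elif np.random.random() < ev_p[v]:
                                    deme[i] = ev_b[v]
                                else:
                                    deme[i] = ev_c[v]
            if alive <= 1:
                break
            t = epoch_times[e]
            t_end = epoch_times[e + 1]
            for d in range(n_demes):
                kd[d] = 0
            for i in range(alive):
                kd[deme[i]] += 1
            while alive > 1:
                tot = 0.0
                for d in range(n_demes):
                    crate[d] = 0.5 * kd[d] * (kd[d] - 1) / sizes[e, d]
                    mo = 0.0
                    for b in range(n_demes):
                        mo += mig[e, d, b]
                    mout[d] = mo
                    mrate[d] = kd[d] * mo
                    tot += crate[d] + mrate[d]
                if tot <= 0.0:
                    if t_end >= 1e29:
                        return -1  # no common root reachable
                    t = t_end
                    break
                dt = -np.log(np.random.random()) / tot
                if t + dt >= t_end:
                    t = t_end
                    break
                t += dt
                r = np.random.random() * tot
                acc = 0.0
                for d in range(n_demes):
                    acc += crate[d]
                    if r < acc:
                        # coalescence in deme d: pick an unordered pair
                        u = int(np.random.random() * kd[d])
                        w = int(np.random.random() * (kd[d] - 1))
                        if w >= u:
                            w += 1
                        ii = -1
                        jj = -1
                        seen = 0
                        for i in range(alive):
                            if deme[i] == d:
                                if seen == u:
                                    ii = i
                                if seen == w:
                                    jj = i
                                seen += 1
                        out[fidx[ii]] += t - born[ii]
                        out[fidx[jj]] += t - born[jj]
                        cnt[ii, 0] += cnt[jj, 0]
                        cnt[ii, 1] += cnt[jj, 1]
                        cnt[ii, 2] += cnt[jj, 2]
                        fidx[ii] = (
                            cnt[ii, 0] * strides[0]
                            + cnt[ii, 1] * strides[1]
                            + cnt[ii, 2] * strides[2]
                        )
                        born[ii] = t
                        last = alive - 1
                        deme[jj] = deme[last]
                        cnt[jj, 0] = cnt[last, 0]
                        cnt[jj, 1] = cnt[last, 1]
                        cnt[jj, 2] = cnt[last, 2]
                        fidx[jj] = fidx[last]
                        born[jj] = born[last]
                        kd[d] -= 1
                        alive -= 1
                        break
                    acc += mrate[d]
                    if r < acc:
                        # migration out of deme d: pick lineage, then target
                        u = int(np.random.random() * kd[d])
                        ii = -1
                        seen = 0
                        for i in range(alive):
                            if deme[i] == d:
                                if seen == u:
                                    ii = i
                                    break
                                seen += 1
                        r2 = np.random.random() * mout[d]
                        acc2 = 0.0
                        for b in range(n_demes):
                            acc2 += mig[e, d, b]
                            if r2 < acc2:
                                kd[d] -= 1
                                kd[b] += 1
                                deme[ii] = b
                                break
                        break
            if alive <= 1:
                break
    return 0


def _schedule_arrays(sched: EventSchedule):
    ev_epoch = sched.event_epochs()
    kinds = np.array(
        [0 if ev.kind == "move" else 1 for ev in sched.events], dtype=np.int64
    )
    a = np.array([ev.a for ev in sched.events], dtype=np.int64)
    b = np.array([ev.b for ev in sched.events], dtype=np.int64)
    c = np.array([ev.c for ev in sched.events], dtype=np.int64)
    p = np.array([ev.prob for ev in sched.events], dtype=np.float64)
    return ev_epoch, kinds, a, b, c, p


def _branch_spectrum(
    sched: EventSchedule, sample_sizes, n_reps: int, seed_seq: np.random.SeedSequence
) -> np.ndarray:
    n_axes = len(sample_sizes)
    shape = tuple(n + 1 for n in sample_sizes)
    strides3 = np.zeros(3, dtype=np.int64)
    st = 1
    for ax in range(n_axes - 1, -1, -1):
        strides3[ax] = st
        st *= shape[ax]
    n_per_deme = np.zeros(sched.n_demes, dtype=np.int64)
    for ax, n in enumerate(sample_sizes):
        n_per_deme[ax] = n
    out = np.zeros(int(np.prod(shape)), dtype=np.float64)
    seeds = (seed_seq.generate_state(n_reps) & 0x7FFFFFFF).astype(np.int64)
    ev_epoch, kinds, a, b, c, p = _schedule_arrays(sched)
    status = _sim_reps(
        seeds,
        n_per_deme,
        sched.epoch_times,
        sched.sizes,
        sched.mig,
        ev_epoch,
        kinds,
        a,
        b,
        c,
        p,
        strides3,
        out,
    )
    if status != 0:
        raise RuntimeError("schedule never reaches a common root (non-convergent)")
    return out.reshape(shape) / n_reps


def expected_jafs(
    scenario: CompiledScenario | EventSchedule,
    sample_sizes,
    n_reps: int = 20000,
    seed: int | np.random.SeedSequence = 0,
) -> JointSFS:
    """Expected joint SFS per unit theta for a compiled scenario.

    Locus-class spectra are computed with independent seed-derived streams
    and combined by their weights; the orientation mixture (O) is applied
    last.  With a fixed seed the result is bit-reproducible.
    """
    if isinstance(scenario, EventSchedule):
        scenario = CompiledScenario("custom", [(scenario, 1.0)], None, scenario.n_demes)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sample_sizes = tuple(int(n) for n in sample_sizes)
    if any(n < 1 for n in sample_sizes):
        raise ValueError("need at least one sampled chromosome per population")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(scenario.schedules))
    ent = np.zeros(tuple(n + 1 for n in sample_sizes))
    for (sched, w), child in zip(scenario.schedules, children):
        if w == 0.0:
            continue
        ent += w * _branch_spectrum(sched, sample_sizes, n_reps, child)
    s = JointSFS(ent / 2.0, sample_sizes, folded=False)
    if scenario.O is not None:
        s = misorient_jafs(s, scenario.O)
    return s
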