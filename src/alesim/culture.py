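"""Multi-genotype planktonic culture dynamics under periodic bottlenecks.

The evolving culture is modelled as a set of genotypes, each with a fixed
intrinsic exponential growth rate (h^-1).  The feedback controller keeps the
reactor in log phase at all times, so growth is pure exponential per genotype
with no substrate (Monod) term.  Two integration modes are provided:

* deterministic — counts are 64-bit floats multiplied by ``exp(mu*dt)``;
  exact and used for closed-form cross-checks;
* stochastic — counts are integers advanced by a Poisson tau-leap of the
  pure-birth (Yule) process, which scales to the ~1e9-cell reactor while
  remaining unbiased (the per-genotype increment has mean
  ``N*(exp(mu*dt)-1)``, the exact Yule expectation).

Beneficial mutations arrive at ``u`` per cell division and found new
genotypes whose rate is the parent's times ``1+s``.  Bottleneck dilution is
binomial thinning (stochastic) or scalar multiplication (deterministic).
Wall biofilm — the operational nuisance of *Pseudomonas putida* cultivation —
exchanges cells with the planktonic phase and is what the auxiliary-chamber
cleaning cycle removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Maximum mu*dt allowed in one stochastic tau-leap step.  Above this the
#: Poisson approximation to the Yule process degrades; callers split dt.
TAU_LEAP_CAP = 0.05

NO_PARENT = -1


@dataclass(frozen=True)
class Genotype:
    """A lineage with a fixed intrinsic exponential growth rate."""

    id: int
    growth_rate: float  # h^-1
    parent_id: int | None = None
    birth_time: float = 0.0  # hours since run start

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValueError(f"growth_rate must be >= 0, got {self.growth_rate}")


@dataclass(frozen=True)
class MutationModel:
    """Supply of beneficial mutations.

    ``rate_per_division`` is the probability u that a division yields a
    beneficial mutant; ``effect`` selects the fitness-effect distribution:
    a point mass at ``s`` or an exponential with mean ``s``.  A mutant's
    growth rate is its parent's times ``1 + s``.
    """

    rate_per_division: float = 1e-9
    effect: str = "point"  # "point" | "exponential"
    s: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate_per_division <= 1.0:
            raise ValueError("rate_per_division must lie in [0, 1]")
        if self.effect not in ("point", "exponential"):
            raise ValueError(f"unknown effect distribution {self.effect!r}")
        if self.s < 0:
            raise ValueError("fitness effect s must be >= 0")

    def draw_effects(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.effect == "point":
            return np.full(n, self.s)
        return rng.exponential(self.s, size=n)


class Population:
    """Array-backed registry of live genotypes and their cell counts.

    Counts are float64 in deterministic mode and integer-valued in
    stochastic mode.  Extinct lineages are pruned from the live arrays but
    retained in ``extinct`` so the full lineage history can be exported.
    """

    __slots__ = ("ids", "growth_rates", "parent_ids", "birth_times", "counts",
                 "extinct", "_next_id")

    def __init__(self, ids, growth_rates, parent_ids, birth_times, counts,
                 extinct=None, next_id=None):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.growth_rates = np.asarray(growth_rates, dtype=np.float64)
        self.parent_ids = np.asarray(parent_ids, dtype=np.int64)
        self.birth_times = np.asarray(birth_times, dtype=np.float64)
        self.counts = np.asarray(counts)
        self.extinct: list[tuple[int, float, int, float]] = list(extinct or [])
        if len({a.shape[0] for a in (self.ids, self.growth_rates,
                                     self.parent_ids, self.birth_times,
                                     self.counts)}) > 1:
            raise ValueError("population arrays must share one length")
        if self.ids.size and np.unique(self.ids).size != self.ids.size:
            raise ValueError("genotype ids must be unique")
        if np.any(self.growth_rates < 0):
            raise ValueError("growth rates must be >= 0")
        if np.any(self.counts < 0):
            raise ValueError("cell counts must be >= 0")
        self._next_id = int(next_id if next_id is not None
                            else (self.ids.max() + 1 if self.ids.size else 0))

    # -- constructors -----------------------------------------------------
    @classmethod
    def single(cls, count, growth_rate: float) -> "Population":
        """One founding genotype (id 0)."""
        return cls([0], [growth_rate], [NO_PARENT], [0.0], [count])

    @classmethod
    def from_arrays(cls, counts, growth_rates) -> "Population":
        n = len(counts)
        return cls(np.arange(n), growth_rates, np.full(n, NO_PARENT),
                   np.zeros(n), counts)

    # -- queries ----------------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return int(self.ids.size)

    def total(self) -> float:
        return float(self.counts.sum())

    def genotype(self, gid: int) -> Genotype:
        idx = np.flatnonzero(self.ids == gid)
        if idx.size:
            i = int(idx[0])
            parent = int(self.parent_ids[i])
            return Genotype(gid, float(self.growth_rates[i]),
                            None if parent == NO_PARENT else parent,
                            float(self.birth_times[i]))
        for eid, rate, parent, birth in self.extinct:
            if eid == gid:
                return Genotype(eid, rate,
                                None if parent == NO_PARENT else parent, birth)
        raise KeyError(f"unknown genotype id {gid}")

    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts / tot

    def mean_growth_rate(self) -> float:
        """Cell-count-weighted mean of the per-genotype rates."""
        tot = self.counts.sum()
        if tot == 0:
            return 0.0
        return float(np.dot(self.counts, self.growth_rates) / tot)

    def copy(self) -> "Population":
        return Population(self.ids.copy(), self.growth_rates.copy(),
                          self.parent_ids.copy(), self.birth_times.copy(),
                          self.counts.copy(), list(self.extinct),
                          self._next_id)

    # -- mutation/pruning support -----------------------------------------
    def add_genotype(self, count, growth_rate: float, parent_id: int,
                     birth_time: float) -> int:
        gid = self._next_id
        self._next_id += 1
        self.ids = np.append(self.ids, gid)
        self.growth_rates = np.append(self.growth_rates, growth_rate)
        self.parent_ids = np.append(self.parent_ids, parent_id)
        self.birth_times = np.append(self.birth_times, birth_time)
        self.counts = np.append(self.counts, np.asarray(count,
                                                        self.counts.dtype))
        return gid

    def prune(self) -> "Population":
        """Drop zero-count genotypes, archiving them in ``extinct``."""
        dead = self.counts == 0
        if not dead.any():
            return self
        for i in np.flatnonzero(dead):
            self.extinct.append((int(self.ids[i]), float(self.growth_rates[i]),
                                 int(self.parent_ids[i]),
                                 float(self.birth_times[i])))
        keep = ~dead
        return Population(self.ids[keep], self.growth_rates[keep],
                          self.parent_ids[keep], self.birth_times[keep],
                          self.counts[keep], self.extinct, self._next_id)

    def lineage_table(self) -> pd.DataFrame:
        """All genotypes ever observed: live rows carry their final count."""
        rows = [(int(g), float(r), int(p), float(b), c)
                for g, r, p, b, c in zip(self.ids, self.growth_rates,
                                         self.parent_ids, self.birth_times,
                                         self.counts)]
        rows += [(g, r, p, b, 0) for g, r, p, b in self.extinct]
        df = pd.DataFrame(rows, columns=["genotype_id", "growth_rate",
                                         "parent_id", "birth_time_h",
                                         "final_count"])
        df = df.sort_values("genotype_id", ignore_index=True)
        return df[["genotype_id", "parent_id", "birth_time_h", "growth_rate",
                   "final_count"]]


# ---------------------------------------------------------------------------
# growth

def grow_deterministic(pop: Population, dt: float) -> Population:
    """Advance every genotype by ``exp(mu*dt)``; exact for any dt >= 0."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    out = pop.copy()
    out.counts = pop.counts * np.exp(pop.growth_rates * dt)
    return out


def grow_stochastic(pop: Population, dt: float,
                    rng: np.random.Generator) -> Population:
    """One Poisson tau-leap of the pure-birth process.

    Each genotype's count is incremented by a Poisson draw with mean
    ``N*(exp(mu*dt)-1)`` — the exact expectation of a Yule process — so the
    leap is unbiased.  Requires ``mu*dt <= TAU_LEAP_CAP`` for every genotype.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if pop.ids.size:
        worst = float((pop.growth_rates * dt).max())
        if worst > TAU_LEAP_CAP + 1e-12:
            raise ValueError(
                f"mu*dt = {worst:.4g} exceeds the tau-leap cap "
                f"{TAU_LEAP_CAP}; split dt into sub-steps of at most "
                f"{TAU_LEAP_CAP / float(pop.growth_rates.max()):.4g} h")
    out = pop.copy()
    births = rng.poisson(pop.counts * np.expm1(pop.growth_rates * dt))
    out.counts = pop.counts.astype(np.int64) + births
    return out


def spawn_mutants(pop: Population, divisions, model: MutationModel,
                  time: float, rng: np.random.Generator) -> Population:
    """Convert a Poisson number of the interval's divisions into new lineages.

    ``divisions`` holds the per-genotype number of divisions in the step just
    taken (for a pure-birth process, the count increment).  Each mutant cell
    founds its own genotype with rate ``parent*(1+s)`` and is moved out of the
    parent's count, conserving the total.
    """
    if model.rate_per_division == 0.0 or pop.ids.size == 0:
        return pop
    divisions = np.maximum(np.asarray(divisions, dtype=np.float64), 0.0)
    n_mut = rng.poisson(model.rate_per_division * divisions)
    n_mut = np.minimum(n_mut, np.floor(pop.counts).astype(np.int64))
    if not n_mut.any():
        return pop
    out = pop.copy()
    one = np.asarray(1, dtype=out.counts.dtype)
    for i in np.flatnonzero(n_mut):
        parent_rate = float(out.growth_rates[i])
        parent_id = int(out.ids[i])
        effects = model.draw_effects(int(n_mut[i]), rng)
        for s in effects:
            out.counts[i] -= one
            out.add_genotype(1, parent_rate * (1.0 + float(s)), parent_id,
                             time)
    return out


def dilute(pop: Population, survival_prob: float,
           rng: np.random.Generator | None = None) -> Population:
    """Bottleneck the culture: each cell survives with ``survival_prob``.

    Stochastic mode (rng given) thins each genotype independently with a
    binomial draw; deterministic mode multiplies counts.  Genotypes reaching
    zero are pruned (their lineage record is kept).
    """
    if not 0.0 < survival_prob <= 1.0:
        raise ValueError(
            f"survival_prob must lie in (0, 1], got {survival_prob}")
    out = pop.copy()
    if rng is None:
        out.counts = pop.counts * survival_prob
    else:
        out.counts = rng.binomial(pop.counts.astype(np.int64), survival_prob)
    return out.prune()


# ---------------------------------------------------------------------------
# biofilm

@dataclass
class BiofilmState:
    """Wall-adhered biomass per chamber, exchanging cells with the culture.

    Dynamics of the adhered pool B in the active chamber:
    ``dB/dt = k_a*N_total + (mu_f - k_s)*B`` with attachment rate ``k_a``
    (h^-1, fraction of planktonic cells adhering per hour), detachment
    (shedding) rate ``k_s`` (h^-1) and film growth rate ``mu_f`` (h^-1).
    In the default aggregate mode each chamber's film is one pool; with
    ``per_genotype=True`` film composition is tracked per lineage.
    """

    attach_rate: float = 2e-6
    detach_rate: float = 0.05
    growth_rate: float = 0.10
    per_genotype: bool = False
    film: dict[str, float] = field(default_factory=lambda: {"A": 0.0, "B": 0.0})
    film_by_genotype: dict[str, dict[int, float]] = field(
        default_factory=lambda: {"A": {}, "B": {}})

    def __post_init__(self) -> None:
        for name in ("attach_rate", "detach_rate", "growth_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.film.values()):
            raise ValueError("adhered biomass must be >= 0")

    def adhered(self, chamber: str) -> float:
        if self.per_genotype:
            return float(sum(self.film_by_genotype[chamber].values()))
        return float(self.film[chamber])

    def clean(self, chamber: str) -> None:
        """NaOH/water wash: adhered biomass of the chamber drops to zero."""
        self.film[chamber] = 0.0
        self.film_by_genotype[chamber] = {}


def update_biofilm(bf: BiofilmState, pop: Population, dt: float,
                   chamber: str = "A",
                   rng: np.random.Generator | None = None,
                   ) -> tuple[BiofilmState, Population]:
    """One explicit-Euler exchange step between wall film and culture.

    Attachment moves ``k_a*N_i*dt`` cells per genotype from the planktonic
    phase onto the walls; the film grows at ``mu_f``; shedding returns
    ``k_s*B*dt`` cells to the planktonic phase (proportionally to film
    composition in per-genotype mode, to planktonic composition in aggregate
    mode).  Cell number is conserved exactly when ``mu = mu_f = 0``.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    attach_frac = bf.attach_rate * dt
    if attach_frac > 1.0:
        raise ValueError("attach_rate*dt > 1; use smaller sub-steps")
    out = pop.copy()
    new = replace(bf, film=dict(bf.film),
                  film_by_genotype={c: dict(d)
                                    for c, d in bf.film_by_genotype.items()})

    # attachment: planktonic -> wall
    if rng is None:
        attached = pop.counts * attach_frac
    else:
        attached = rng.binomial(pop.counts.astype(np.int64), attach_frac)
    out.counts = out.counts - attached
    if bf.per_genotype:
        pool = new.film_by_genotype[chamber]
        for gid, a in zip(pop.ids, np.atleast_1d(attached)):
            if a:
                pool[int(gid)] = pool.get(int(gid), 0.0) + float(a)
        # film growth then shedding, per lineage
        growth = math.exp(bf.growth_rate * dt) if bf.growth_rate else 1.0
        shed_total = 0.0
        shed_by_gid: dict[int, float] = {}
        for gid in list(pool):
            pool[gid] *= growth
            shed = bf.detach_rate * pool[gid] * dt
            shed = min(shed, pool[gid])
            pool[gid] -= shed
            shed_by_gid[gid] = shed
            shed_total += shed
        if shed_total > 0:
            out = _return_shed(out, shed_by_gid, rng)
    else:
        total_attached = float(np.sum(attached))
        film = new.film[chamber] + total_attached
        film *= math.exp(bf.growth_rate * dt) if bf.growth_rate else 1.0
        shed = min(bf.detach_rate * film * dt, film)
        film -= shed
        new.film[chamber] = film
        if shed > 0 and out.counts.size:
            freqs = out.frequencies()
            if freqs.sum() == 0:  # no planktonic cells left: seed genotype 0
                freqs = np.zeros_like(freqs)
                freqs[0] = 1.0
            if rng is None:
                out.counts = out.counts + shed * freqs
            else:
                n_shed = min(int(rng.poisson(shed)), int(math.floor(film + shed)))
                if n_shed:
                    out.counts = out.counts + rng.multinomial(n_shed, freqs)
                    new.film[chamber] = max(film + shed - n_shed, 0.0)
    return new, out


def _return_shed(pop: Population, shed_by_gid: dict[int, float],
                 rng: np.random.Generator | None) -> Population:
    """Return per-genotype shed cells to the planktonic phase."""
    id_to_idx = {int(g): i for i, g in enumerate(pop.ids)}
    for gid, shed in shed_by_gid.items():
        amount = shed if rng is None else rng.poisson(shed)
        if amount == 0:
            continue
        if gid in id_to_idx:
            pop.counts[id_to_idx[gid]] += np.asarray(amount,
                                                     pop.counts.dtype)
        else:  # lineage extinct planktonically: re-seed it from the wall
            g = pop.genotype(gid)
            pop.extinct = [e for e in pop.extinct if e[0] != gid]
            pop.ids = np.append(pop.ids, gid)
            pop.growth_rates = np.append(pop.growth_rates, g.growth_rate)
            pop.parent_ids = np.append(
                pop.parent_ids, NO_PARENT if g.parent_id is None else g.parent_id)
            pop.birth_times = np.append(pop.birth_times, g.birth_time)
            pop.counts = np.append(pop.counts,
                                   np.asarray(amount, pop.counts.dtype))
            id_to_idx[gid] = pop.counts.size - 1
    return pop


# ---------------------------------------------------------------------------
# composite step

def advance_culture(pop: Population, dt: float, *,
                    biofilm: BiofilmState | None = None,
                    chamber: str = "A",
                    mutation: MutationModel | None = None,
                    rng: np.random.Generator | None = None,
                    mutation_rng: np.random.Generator | None = None,
                    time0: float = 0.0,
                    ) -> tuple[Population, BiofilmState | None]:
    """Advance the culture by ``dt`` hours, sub-stepping to honour the
    tau-leap cap, spawning mutants from the divisions of each sub-step and
    exchanging cells with the wall film.

    ``rng=None`` selects deterministic growth and wall exchange; mutation,
    being inherently stochastic, draws from ``mutation_rng`` (defaulting to
    ``rng``) and requires one when its rate is non-zero.
    """
    if dt == 0 or pop.ids.size == 0:
        return pop, biofilm
    mutation_rng = mutation_rng if mutation_rng is not None else rng
    elapsed = 0.0
    while elapsed < dt - 1e-12 * dt:
        # recomputed every step: a freshly spawned faster mutant tightens
        # the cap for the remainder of the interval
        mu_max = float(pop.growth_rates.max()) if pop.ids.size else 0.0
        remaining = dt - elapsed
        if mu_max > 0:
            n_left = max(1, math.ceil(mu_max * remaining / TAU_LEAP_CAP))
            sub = remaining / n_left
        else:
            sub = remaining
        before = pop.counts
        grown = (grow_deterministic(pop, sub) if rng is None
                 else grow_stochastic(pop, sub, rng))
        if mutation is not None and mutation.rate_per_division > 0:
            if mutation_rng is None:
                raise ValueError("mutation requires an rng (it is stochastic)")
            divisions = grown.counts - before
            grown = spawn_mutants(grown, divisions, mutation,
                                  time0 + elapsed + sub, mutation_rng)
        if biofilm is not None:
            biofilm, grown = update_biofilm(biofilm, grown, sub, chamber, rng)
        pop = grown
        elapsed += sub
    return pop, biofilm
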