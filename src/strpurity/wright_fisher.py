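"""Forward-time Wright-Fisher simulation of interruption dynamics.

Haploid Wright-Fisher resampling with multiplicative fitness over a
population of STR alleles at a single locus.  An allele is a repeat of
``length_bp`` bases carrying zero or more interruptions, each with a
coding consequence (silent or missense) drawn once at its origin from the
motif's mutational-space proportions.  Slippage mutates an allele with
probability ``mu_slip * longest_pure_stretch / motif_len`` per generation
(slippage scales with the pure tract, so interruptions act as cis-linked
anti-mutators); a slippage event gains or loses one motif with equal
odds, and every gained nucleotide becomes an interruption with
probability ``gain_rate``.  Contractions that span an interruption delete
it.

Fitness is multiplicative: ``(1 - s_length)`` per motif of deviation from
the optimum (initial) length, ``(1 - s_missense)`` per missense
interruption and ``(1 - s_silent)`` per silent interruption.  Comparing a
neutral scenario with a constrained one tests the two qualitative
predictions of the anti-mutator model: silent interruptions rise in
frequency under length constraint, and missense interruptions are purged
under coding constraint.

Rates and selection coefficients here are desk-scale calibrations chosen
so the planted dynamics separate within hundreds of generations in
populations of ~1,000; they are not estimates of human parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import interruption_consequence_probs

__all__ = ["FitnessModel", "WFParams", "PopulationState", "run_replicate", "simulate_fig1"]


@dataclass(frozen=True)
class FitnessModel:
    """Selection per motif-length deviation and per interruption class."""

    s_length: float = 0.0
    s_missense: float = 0.0
    s_silent: float = 0.0

    def __post_init__(self) -> None:
        for s in (self.s_length, self.s_missense, self.s_silent):
            if not 0 <= s < 1:
                raise ValueError("selection coefficients must be in [0, 1)")


@dataclass(frozen=True)
class WFParams:
    N: int = 1000
    motif: str = "CAG"
    init_copies: int = 15
    mu_slip: float = 1e-2  # per motif copy of pure stretch, per generation
    gain_rate: float = 1e-3  # interruption probability per added nucleotide
    point_rate: float = 3e-3  # per-allele rate of interruption by point substitution

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size must be at least 2")


@dataclass
class PopulationState:
    """Per-individual allele state (parallel arrays plus interruption lists)."""

    generation: int
    length_bp: np.ndarray
    interruptions: list[tuple[tuple[int, str], ...]]  # (bp position, 's'|'m')
    longest_pure: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def N(self) -> int:
        return len(self.length_bp)

    def counts(self, consequence: str) -> np.ndarray:
        return np.array([sum(c == consequence for _, c in ints)
                         for ints in self.interruptions])

    def interrupted_frequency(self, consequence: str) -> float:
        return float(np.mean([any(c == consequence for _, c in ints)
                              for ints in self.interruptions]))


def _longest_pure(length: int, positions: tuple[int, ...]) -> int:
    if not positions:
        return length
    best = positions[0]
    prev = positions[0]
    for p in positions[1:]:
        best = max(best, p - prev - 1)
        prev = p
    return max(best, length - prev - 1)


def _init_population(params: WFParams) -> PopulationState:
    L = params.init_copies * len(params.motif)
    return PopulationState(
        generation=0,
        length_bp=np.full(params.N, L, dtype=np.int64),
        interruptions=[() for _ in range(params.N)],
        longest_pure=np.full(params.N, L, dtype=np.int64),
    )


def _mutate_one(
    length: int,
    ints: tuple[tuple[int, str], ...],
    params: WFParams,
    p_sil: float,
    rng: np.random.Generator,
) -> tuple[int, tuple[tuple[int, str], ...]]:
    """One slippage event: gain or lose one motif, maybe gaining interruptions."""
    p = len(params.motif)
    if rng.random() < 0.5 or length <= 2 * p:  # expansion (forced at minimum length)
        at = int(rng.integers(0, length + 1))
        new = tuple(sorted(((pos + p if pos >= at else pos), c) for pos, c in ints))
        length += p
        gained = []
        for off in range(p):
            if rng.random() < params.gain_rate:
                cons = "s" if rng.random() < p_sil else "m"
                gained.append((at + off, cons))
        if gained:
            new = tuple(sorted([*new, *gained]))
        return length, new
    # contraction: delete a motif-length segment; spanned interruptions vanish
    at = int(rng.integers(0, length - p + 1))
    kept = []
    for pos, c in ints:
        if pos < at:
            kept.append((pos, c))
        elif pos >= at + p:
            kept.append((pos - p, c))
    return length - p, tuple(kept)


def run_replicate(
    params: WFParams,
    fitness: FitnessModel,
    generations: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Evolve one population and return its final state."""
    motif_len = len(params.motif)
    L0 = params.init_copies * motif_len
    p_sil, _ = interruption_consequence_probs(params.motif)
    state = _init_population(params)
    n_sil = np.zeros(params.N)
    n_mis = np.zeros(params.N)
    for gen in range(generations):
        dev = np.abs(state.length_bp - L0) // motif_len
        w = (
            (1 - fitness.s_length) ** dev
            * (1 - fitness.s_missense) ** n_mis
            * (1 - fitness.s_silent) ** n_sil
        )
        probs = w / w.sum()
        idx = rng.choice(params.N, size=params.N, p=probs)
        state = PopulationState(
            generation=gen + 1,
            length_bp=state.length_bp[idx],
            interruptions=[state.interruptions[i] for i in idx],
            longest_pure=state.longest_pure[idx],
        )
        n_sil, n_mis = n_sil[idx], n_mis[idx]
        p_mut = params.mu_slip * state.longest_pure / motif_len
        mutants = np.flatnonzero(rng.random(params.N) < p_mut)
        for i in mutants:
            length, ints = _mutate_one(
                int(state.length_bp[i]), state.interruptions[i], params, p_sil, rng
            )
            _set(state, n_sil, n_mis, i, length, ints)
        # interruptions arising by single-base substitution, independent of slippage
        if params.point_rate:
            hits = np.flatnonzero(rng.random(params.N) < params.point_rate)
            for i in hits:
                length = int(state.length_bp[i])
                ints = state.interruptions[i]
                pos = int(rng.integers(0, length))
                if any(p == pos for p, _ in ints):
                    continue
                cons = "s" if rng.random() < p_sil else "m"
                _set(state, n_sil, n_mis, i, length, tuple(sorted([*ints, (pos, cons)])))
    return state


def _set(state: PopulationState, n_sil: np.ndarray, n_mis: np.ndarray,
         i: int, length: int, ints: tuple[tuple[int, str], ...]) -> None:
    state.length_bp[i] = length
    state.interruptions[i] = ints
    state.longest_pure[i] = _longest_pure(length, tuple(p for p, _ in ints))
    n_sil[i] = sum(c == "s" for _, c in ints)
    n_mis[i] = sum(c == "m" for _, c in ints)


def simulate_fig1(
    fitness_neutral: FitnessModel,
    fitness_constrained: FitnessModel,
    params: WFParams | None = None,
    generations: int = 500,
    replicates: int = 200,
    seed: int = 0,
) -> dict[str, dict[str, np.ndarray]]:
    """Replicate final interruption frequencies for two selection scenarios.

    Both scenarios share the mutational parameters; only fitness differs.
    Returns per-scenario arrays (one entry per replicate) of the final
    population frequency of alleles carrying at least one silent and at
    least one missense interruption.
    """
    params = params or WFParams()
    out: dict[str, dict[str, np.ndarray]] = {}
    for scen_idx, (name, fitness) in enumerate(
        (("neutral", fitness_neutral), ("constrained", fitness_constrained))
    ):
        rng = np.random.default_rng([seed % (2**31), scen_idx])
        sil = np.empty(replicates)
        mis = np.empty(replicates)
        for r in range(replicates):
            final = run_replicate(params, fitness, generations, rng)
            sil[r] = final.interrupted_frequency("s")
            mis[r] = final.interrupted_frequency("m")
        out[name] = {"silent": sil, "missense": mis}
    return out
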