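"""Ensemble selection against an experimental SAXS profile.

Two selectors over a scored conformer pool:

* a Jaccard threshold (keep every frame scoring strictly above tau,
  mirroring the "above 0.996" cut used to pick hexagonally packed
  frames), and
* an EOM-style genetic algorithm over fixed-size multisets of frame
  indices, whose fitness is the fit of the unweighted average of the
  member profiles to the experimental curve.

Because scattering from a population is the population-weighted mean
intensity, ensemble averaging happens in intensity space, and ensemble
weights emerge from multiplicity in the GA's multisets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .fit_scoring import FitResult, align_profiles, fit_profiles
from .model_gen import ConformerPool
from .saxs_forward import SaxsConfig, ScatteringProfile, compute_profile


@dataclass
class ScoreSeries:
    """Per-frame fit statistics with cached per-frame profiles.

    ``profiles`` holds the unscaled calculated intensities of every
    frame, aligned on the filtered experimental q-grid, so selectors can
    average members without re-running the Debye sum.
    """

    frame_index: np.ndarray
    results: List[FitResult]
    profiles: np.ndarray            # (n_frames, n_q)
    exp: ScatteringProfile          # filtered experimental profile

    @property
    def jaccard(self) -> np.ndarray:
        return np.array([r.jaccard for r in self.results])

    @property
    def chi2(self) -> np.ndarray:
        return np.array([r.chi2_reduced for r in self.results])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_index": self.frame_index,
            "jaccard": self.jaccard,
            "chi2_reduced": self.chi2,
            "scale": [r.scale for r in self.results],
        })

    def __len__(self) -> int:
        return len(self.frame_index)


@dataclass
class Ensemble:
    """A multiset of frames with weights summing to 1 and its average fit."""

    member_indices: np.ndarray
    weights: np.ndarray
    avg_profile: Optional[ScatteringProfile]
    fit: Optional[FitResult]
    fitness_history: Optional[np.ndarray] = None

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.member_indices) != len(self.weights):
            raise ValueError("weights length mismatch")
        if len(self.weights) and abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for ensemble optimisation."""

    ensemble_size: int = 20
    population: int = 50
    generations: int = 500
    mutation_rate: float = 0.1
    crossover_rate: float = 0.8
    elitism: int = 2
    tournament: int = 3
    rng_seed: int = 0
    fitness: str = "auto"    # auto | chi2 | one_minus_jaccard

    def __post_init__(self):
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.crossover_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population <= self.elitism:
            raise ValueError("population must exceed elitism")
        if self.fitness not in ("auto", "chi2", "one_minus_jaccard"):
            raise ValueError(f"unknown fitness {self.fitness!r}")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_trajectory(pool: ConformerPool, exp: ScatteringProfile,
                     cfg: SaxsConfig, hydration: bool = True) -> ScoreSeries:
    """Debye profile and fit statistics for every frame, in frame order."""
    cached = []
    results = []
    exp_f = None
    for frame in pool.frames:
        calc = compute_profile(frame, cfg, hydration=hydration)
        calc_a, exp_f, _ = align_profiles(calc, exp)
        cached.append(calc_a.intensity)
        results.append(fit_profiles(exp, calc))
    return ScoreSeries(pool.frame_index.copy(), results,
                       np.array(cached), exp_f)


def ensemble_average_profile(scores: ScoreSeries,
                             indices: Sequence[int]) -> ScatteringProfile:
    """Pointwise mean intensity over member frames (multiset semantics)."""
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        raise ValueError("empty ensemble")
    pos = np.searchsorted(scores.frame_index, indices)
    if np.any(pos >= len(scores)) or np.any(scores.frame_index[pos] != indices):
        raise IndexError("index not in scored pool")
    mean = scores.profiles[pos].mean(axis=0)
    return ScatteringProfile(scores.exp.q, mean, label="ensemble average")


def _ensemble_fit(scores: ScoreSeries, indices: np.ndarray) -> FitResult:
    avg = ensemble_average_profile(scores, indices)
    return fit_profiles(scores.exp, avg)


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def select_by_threshold(scores: ScoreSeries, tau: float) -> Ensemble:
    """Uniform-weight ensemble of all frames with J strictly above tau.

    An empty result (e.g. tau = 1) is a valid outcome, not an error.
    """
    if tau > 1:
        raise ValueError("tau must be <= 1")
    mask = scores.jaccard > tau
    members = scores.frame_index[mask]
    if len(members) == 0:
        return Ensemble(np.array([], dtype=int), np.array([]), None, None)
    weights = np.full(len(members), 1.0 / len(members))
    avg = ensemble_average_profile(scores, members)
    return Ensemble(members, weights, avg, fit_profiles(scores.exp, avg))


def ga_optimize(scores: ScoreSeries, ga: GAConfig) -> Ensemble:
    """EOM-style genetic algorithm over multisets of frame indices.

    Chromosomes are sorted multisets of ``ensemble_size`` frame indices
    (repeats allowed).  Fitness is the reduced chi^2 of the member
    average against experiment when sigmas are available (or when
    forced), else 1 - J; minimised via tournament selection,
    single-point crossover on the sorted lists, per-gene mutation to a
    uniform random frame, and elitism.  Returns the best multiset ever
    seen; deterministic under the configured seed.
    """
    n_frames = len(scores)
    if n_frames < 1:
        raise ValueError("empty scored pool")
    use_chi2 = ga.fitness == "chi2" or (
        ga.fitness == "auto" and scores.exp.sigma is not None)
    if use_chi2 and scores.exp.sigma is None:
        raise ValueError("chi2 fitness requires experimental sigmas")
    rng = np.random.default_rng(ga.rng_seed)

    def fitness(chrom: np.ndarray) -> float:
        fit = _ensemble_fit(scores, scores.frame_index[chrom])
        return fit.chi2_reduced if use_chi2 else 1.0 - fit.jaccard

    pop = [np.sort(rng.integers(0, n_frames, ga.ensemble_size))
           for _ in range(ga.population)]
    fits = np.array([fitness(c) for c in pop])
    best_i = int(np.argmin(fits))
    best, best_fit = pop[best_i].copy(), float(fits[best_i])
    history = [best_fit]

    for _ in range(ga.generations):
        order = np.argsort(fits)
        new_pop = [pop[i].copy() for i in order[:ga.elitism]]
        while len(new_pop) < ga.population:
            a = _tournament(rng, fits, ga.tournament)
            b = _tournament(rng, fits, ga.tournament)
            c1, c2 = pop[a].copy(), pop[b].copy()
            if rng.random() < ga.crossover_rate and ga.ensemble_size > 1:
                cut = int(rng.integers(1, ga.ensemble_size))
                c1, c2 = (np.sort(np.concatenate([pop[a][:cut], pop[b][cut:]])),
                          np.sort(np.concatenate([pop[b][:cut], pop[a][cut:]])))
            for child in (c1, c2):
                mut = rng.random(ga.ensemble_size) < ga.mutation_rate
                if mut.any():
                    child[mut] = rng.integers(0, n_frames, int(mut.sum()))
                    child.sort()
                if len(new_pop) < ga.population:
                    new_pop.append(child)
        pop = new_pop
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best, best_fit = pop[gen_best].copy(), float(fits[gen_best])
        history.append(best_fit)

    members = scores.frame_index[best]
    weights = np.full(len(members), 1.0 / len(members))
    avg = ensemble_average_profile(scores, members)
    return Ensemble(members, weights, avg, fit_profiles(scores.exp, avg),
                    fitness_history=np.array(history))


def _tournament(rng: np.random.Generator, fits: np.ndarray, k: int) -> int:
    contenders = rng.integers(0, len(fits), k)
    return int(contenders[np.argmin(fits[contenders])])
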