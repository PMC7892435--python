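"""Moment estimators of founder-allele age from LD decay.

Two estimators:

* ``risch_age`` — closed form g = ln(delta) / ln(1 - theta), from the
  expected per-generation decay of the ancestral allele on disease
  chromosomes.
* ``markov_age`` — a per-generation transition matrix K = theta*R + mu*M +
  (1 - theta - mu)*I is iterated on the ancestral state vector until the
  observed ancestral-allele proportion is reached; the number of iterations
  is the age. This corrects the LD decay for stepwise marker mutation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .haplotype_io import HaplotypeSet, MarkerMap
from .ld_stats import AncestralHaplotype, ancestral_proportion, allele_frequencies, compute_delta

log = logging.getLogger(__name__)

MAP_FUNCTIONS = ("linear", "haldane", "kosambi")

#: default per-meiosis mutation rates by repeat-unit length (bp)
MU_BY_REPEAT_UNIT = {2: 5.6e-4, 4: 2.1e-3}


class NonInformativeMarkerError(ValueError):
    """delta <= 0: the marker carries no LD signal for dating."""


class ConvergenceError(RuntimeError):
    """The Markov iteration cannot reach the observed proportion."""


_warned_linear: set[float] = set()  # warn once per distance, not per call


def cm_to_theta(dist_cM: float, map_function: str = "linear") -> float:
    """Convert genetic distance to a recombination fraction.

    ``linear`` uses theta = cM/100 as-is, with no 0.5 cap (a warning is
    logged above 0.5); this is the convention that reproduces the published
    moment-method summary, where even a 54.8 cM marker enters linearly.
    """
    if not dist_cM > 0:
        raise ValueError(f"non-positive distance: {dist_cM}")
    d = dist_cM / 100.0  # Morgans
    if map_function == "linear":
        if d > 0.5 and dist_cM not in _warned_linear:
            _warned_linear.add(dist_cM)
            log.warning("linear theta %.3f exceeds 0.5 (distance %.2f cM)", d, dist_cM)
        return d
    if map_function == "haldane":
        return 0.5 * (1.0 - math.exp(-2.0 * d))
    if map_function == "kosambi":
        return 0.5 * math.tanh(2.0 * d)
    raise ValueError(f"unknown map function {map_function!r}")


def bp_to_cm(dist_bp: float, factor: float = 1.17) -> float:
    """Physical to genetic distance via a cM/Mb conversion factor."""
    if dist_bp < 0:
        raise ValueError(f"negative distance: {dist_bp}")
    return dist_bp * factor / 1e6


def risch_age(delta: float, theta: float) -> float:
    """Moment age g = ln(delta) / ln(1 - theta), in (real-valued) generations."""
    if delta <= 0:
        raise NonInformativeMarkerError(f"delta must be positive, got {delta}")
    if delta > 1:
        raise ValueError(f"delta must be <= 1, got {delta}")
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    if delta == 1.0:
        return 0.0
    return math.log(delta) / math.log(1.0 - theta)


def aggregate_moment(per_marker_g: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of per-marker age estimates."""
    g = np.asarray(per_marker_g, dtype=float)
    if g.size < 2 or not np.all(np.isfinite(g)):
        raise ValueError("need at least two finite per-marker estimates")
    return float(g.mean()), float(g.std(ddof=1))


@dataclass(frozen=True)
class MarkovModel:
    """Per-generation allele transformation at one marker."""

    states: tuple[int, ...]
    theta: float
    mu: float
    control_freqs: np.ndarray
    K: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution of K (left eigenvector for eigenvalue 1)."""
        vals, vecs = np.linalg.eig(self.K.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


def build_markov(
    states: Sequence[int],
    theta: float,
    mu: float,
    control_freqs: Sequence[float],
) -> MarkovModel:
    """Build K = theta*R + mu*M + (1 - theta - mu)*I.

    R replaces the allele with a draw from the control frequency vector; M is
    a stepwise +/-1 mutation with probability 1/2 each, reflecting inward at
    the boundaries of the state range; I is no event.
    """
    states = tuple(int(s) for s in states)
    if sorted(states) != list(states) or len(set(states)) != len(states):
        raise ValueError("states must be strictly increasing")
    q = np.asarray(control_freqs, dtype=float)
    if q.shape != (len(states),):
        raise ValueError("control_freqs length must match states")
    if abs(q.sum() - 1.0) > 1e-9 or np.any(q < 0):
        raise ValueError(f"control frequencies must form a probability vector, sum={q.sum()}")
    if theta < 0 or mu < 0 or theta + mu > 1:
        raise ValueError(f"require theta, mu >= 0 and theta + mu <= 1 (got {theta}, {mu})")
    n = len(states)
    R = np.tile(q, (n, 1))
    M = np.zeros((n, n))
    if n == 1:
        M[0, 0] = 1.0  # nowhere to step
    else:
        for i in range(n):
            up = i + 1 if i + 1 < n else i - 1  # reflect inward at boundary
            down = i - 1 if i - 1 >= 0 else i + 1
            M[i, up] += 0.5
            M[i, down] += 0.5
    K = theta * R + mu * M + (1.0 - theta - mu) * np.eye(n)
    return MarkovModel(states=states, theta=theta, mu=mu, control_freqs=q, K=K)


def markov_age(
    p_obs: float,
    model: MarkovModel,
    anc_states: Iterable[int],
    max_iter: int = 10_000,
) -> int:
    """Smallest t >= 0 with ancestral mass of v0 @ K^t at or below p_obs.

    v0 is a point mass on the ancestral state (split equally when the
    ancestral set holds several states).
    """
    if not 0 < p_obs <= 1:
        raise ValueError(f"p_obs must be in (0, 1], got {p_obs}")
    anc_idx = [model.states.index(int(s)) for s in anc_states]
    if not anc_idx:
        raise ValueError("empty ancestral state set")
    v = np.zeros(len(model.states))
    v[anc_idx] = 1.0 / len(anc_idx)
    for t in range(max_iter + 1):
        if float(v[anc_idx].sum()) <= p_obs + 1e-12:
            return t
        v = v @ model.K
    stationary_mass = float(model.stationary[anc_idx].sum())
    raise ConvergenceError(
        f"ancestral mass did not fall to {p_obs} within {max_iter} iterations; "
        f"stationary ancestral mass is {stationary_mass:.4f}"
    )


@dataclass(frozen=True)
class AgeEstimate:
    """A dated point estimate of founder-allele age."""

    method: str
    g_point: float
    g_sd: Optional[float]
    ci95: Optional[tuple[float, float]]
    per_marker: Optional[dict[str, float]]
    years: int
    date: int
    years_per_generation: float = 25.0
    anchor_year: int = 1990

    def __post_init__(self) -> None:
        if self.g_point < 0:
            raise ValueError("g_point must be non-negative")
        if self.ci95 is not None and not self.ci95[0] <= self.g_point <= self.ci95[1]:
            raise ValueError("point estimate outside its interval")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "g": self.g_point,
            "g_sd": self.g_sd,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "per_marker": self.per_marker,
            "years": self.years,
            "date": self.date,
            "years_per_generation": self.years_per_generation,
            "anchor_year": self.anchor_year,
        }
        return d


def _finish_estimate(
    method: str,
    g_point: float,
    g_sd: Optional[float],
    per_marker: Optional[dict[str, float]],
    years_per_generation: float,
    anchor_year: int,
    ci95: Optional[tuple[float, float]] = None,
) -> AgeEstimate:
    from .demography_epi import DemographyParams, generations_to_calendar

    params = DemographyParams(
        years_per_generation=years_per_generation, anchor_year=anchor_year
    )
    years, date = generations_to_calendar(g_point, params)
    return AgeEstimate(
        method=method,
        g_point=g_point,
        g_sd=g_sd,
        ci95=ci95,
        per_marker=per_marker,
        years=years,
        date=date,
        years_per_generation=years_per_generation,
        anchor_year=anchor_year,
    )


def _theta_for(marker, map_function: str) -> float:
    return marker.theta if marker.theta is not None else cm_to_theta(marker.dist_cM, map_function)


def risch_from_deltas(
    deltas: Mapping[str, float],
    marker_map: MarkerMap,
    map_function: str = "linear",
    years_per_generation: float = 25.0,
    anchor_year: int = 1990,
) -> AgeEstimate:
    """Risch moment estimate straight from a per-marker delta table.

    This is the path used to re-derive the published summary from the printed
    per-marker delta and distance values, with no haplotype data required.
    """
    per_marker: dict[str, float] = {}
    for name, delta in deltas.items():
        marker = marker_map[name]
        theta = _theta_for(marker, map_function)
        if delta <= 0:
            log.warning("dropping non-informative marker %s (delta=%.3f)", name, delta)
            continue
        per_marker[name] = risch_age(delta, theta)
    if not per_marker:
        raise NonInformativeMarkerError("all markers non-informative")
    if len(per_marker) == 1:
        g_point = next(iter(per_marker.values()))
        log.warning("single informative marker; SD undefined")
        return _finish_estimate(
            "risch", g_point, None, per_marker, years_per_generation, anchor_year
        )
    mean, sd = aggregate_moment(list(per_marker.values()))
    return _finish_estimate("risch", mean, sd, per_marker, years_per_generation, anchor_year)


def moment_pipeline(
    hapset: HaplotypeSet,
    anc: AncestralHaplotype,
    method: str = "risch",
    map_function: str = "linear",
    independent_only: bool = True,
    years_per_generation: float = 25.0,
    anchor_year: int = 1990,
    state_padding: int = 2,
    max_iter: int = 10_000,
) -> AgeEstimate:
    """Full moment-method estimate from phased haplotypes.

    ``risch`` computes delta per marker and applies the closed form;
    ``markov`` iterates the mutation-corrected transition matrix per marker
    until the observed ancestral proportion is reached. Both aggregate
    per-marker ages into mean +/- sample SD and convert to calendar scale.
    """
    if method == "risch":
        table = compute_delta(hapset, anc, independent_only=independent_only)
        deltas = {
            name: float(table.loc[name, "delta"])
            for name in table.index
            if bool(table.loc[name, "informative"])
        }
        dropped = [n for n in table.index if n not in deltas]
        if dropped:
            log.warning("dropping non-informative markers: %s", dropped)
        return risch_from_deltas(
            deltas,
            hapset.map,
            map_function=map_function,
            years_per_generation=years_per_generation,
            anchor_year=anchor_year,
        )
    if method != "markov":
        raise ValueError(f"unknown moment method {method!r}")
    per_marker: dict[str, float] = {}
    for marker in hapset.map:
        name = marker.name
        p_obs, _, _ = ancestral_proportion(
            hapset, anc, name, independent_only=independent_only
        )
        freq_n, _ = allele_frequencies(hapset, "control", name, independent_only=False)
        anc_states = sorted(anc[name])
        observed = sorted(set(freq_n) | set(anc_states))
        lo, hi = observed[0] - state_padding, observed[-1] + state_padding
        states = list(range(lo, hi + 1))
        q = np.array([freq_n.get(s, 0.0) for s in states])
        theta = _theta_for(marker, map_function)
        mu = marker.mu if marker.mu is not None else MU_BY_REPEAT_UNIT[marker.repeat_unit]
        if theta + mu > 1:
            log.warning("skipping marker %s: theta + mu > 1", name)
            continue
        model = build_markov(states, theta, mu, q)
        try:
            per_marker[name] = float(markov_age(p_obs, model, anc_states, max_iter=max_iter))
        except ConvergenceError as exc:
            log.warning("skipping marker %s: %s", name, exc)
    if not per_marker:
        raise NonInformativeMarkerError("no marker yielded a Markov age")
    if len(per_marker) == 1:
        g_point = next(iter(per_marker.values()))
        log.warning("single informative marker; SD undefined")
        return _finish_estimate(
            "markov", g_point, None, per_marker, years_per_generation, anchor_year
        )
    mean, sd = aggregate_moment(list(per_marker.values()))
    return _finish_estimate("markov", mean, sd, per_marker, years_per_generation, anchor_year)
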