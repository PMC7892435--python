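"""Forward-in-time generator of founder-haplotype datasets.

Carrier chromosomes descend from a single founder haplotype through
``g_true`` independent meioses (star genealogy: no shared internal
branches). Per meiosis and per side of the mutation, one uniform draw
determines the surviving founder segment: marker k (at recombination
fraction theta_k from the mutation) stays ancestral if the draw exceeds
theta_k, so survival events are nested outward and each marker survives a
meiosis with probability 1 - theta_k, i.e. all g meioses with probability
(1 - theta_k)^g. Markers beyond the cut take alleles from the control
frequency distribution. Surviving founder alleles mutate by +/-1 repeat
steps at rate mu_k per meiosis. Control chromosomes are drawn marker-wise
from the control frequencies.

This makes the generator the exact null model of the closed-form moment
estimator, so recovery experiments isolate estimator error from model
misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .age_moment import cm_to_theta, moment_pipeline
from .haplotype_io import ChromosomeRecord, HaplotypeSet, MarkerMap, SIDES
from .ld_stats import AncestralHaplotype
from .mrca_inference import BayesConfig, bayes_posterior, mrca_mle


@dataclass(frozen=True)
class SimulationConfig:
    g_true: int
    map: MarkerMap
    founder: Mapping[str, int]  # singleton ancestral allele per marker
    control_freqs: Mapping[str, Mapping[int, float]]
    n_carriers: int = 30
    n_controls: int = 100
    map_function: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_true < 0:
            raise ValueError("g_true must be non-negative")
        if self.n_carriers < 1 or self.n_controls < 0:
            raise ValueError("need at least one carrier and non-negative controls")
        for name in self.map.names:
            if name not in self.founder:
                raise ValueError(f"founder allele missing for marker {name}")
            freqs = self.control_freqs.get(name)
            if freqs is None:
                raise ValueError(f"control frequencies missing for marker {name}")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in freqs.values()):
                raise ValueError(
                    f"control frequencies at {name} must form a probability vector (sum={total})"
                )


def triangular_control_freqs(
    founder_allele: int,
    mode_offset: int = 2,
    half_width: int = 4,
) -> dict[int, float]:
    """Discretized triangular allele distribution around a non-ancestral mode.

    The mode sits ``mode_offset`` repeat units above the founder allele, so
    the founder allele segregates in controls at a moderate frequency —
    enough identity-by-state to exercise the estimators without drowning the
    descent signal.
    """
    mode = founder_allele + mode_offset
    weights = {
        a: half_width + 1 - abs(a - mode)
        for a in range(mode - half_width, mode + half_width + 1)
        if a >= 1
    }
    total = sum(weights.values())
    return {a: w / total for a, w in sorted(weights.items())}


def default_config(
    marker_map: MarkerMap,
    founder: Mapping[str, int],
    g_true: int,
    n_carriers: int = 30,
    n_controls: int = 100,
    seed: int = 0,
) -> SimulationConfig:
    """Convenience constructor with triangular control frequencies."""
    return SimulationConfig(
        g_true=g_true,
        map=marker_map,
        founder=dict(founder),
        control_freqs={
            name: triangular_control_freqs(founder[name]) for name in marker_map.names
        },
        n_carriers=n_carriers,
        n_controls=n_controls,
        seed=seed,
    )


def simulate(config: SimulationConfig) -> HaplotypeSet:
    """Generate a phased carrier/control haplotype set; bit-reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    names = config.map.names
    records: list[ChromosomeRecord] = []

    side_markers = {side: config.map.side_markers(side) for side in SIDES}
    thetas = {
        side: np.array([
            m.theta if m.theta is not None else cm_to_theta(m.dist_cM, config.map_function)
            for m in ms
        ])
        for side, ms in side_markers.items()
    }

    n, g = config.n_carriers, config.g_true
    carrier_alleles: dict[str, np.ndarray] = {}
    for side in SIDES:
        ms = side_markers[side]
        if not ms:
            continue
        th = thetas[side]
        if g > 0:
            # min over meioses of the per-meiosis crossover draw; marker k's
            # founder segment survives all g meioses iff every draw > theta_k
            u_min = rng.random((n, g)).min(axis=1)
        else:
            u_min = np.ones(n)
        for k, marker in enumerate(ms):
            survived = u_min > th[k]
            alleles = np.empty(n, dtype=int)
            founder_allele = config.founder[marker.name]
            if g > 0 and marker.mu > 0:
                n_mut = rng.binomial(g, marker.mu, size=n)
                steps = 2 * rng.binomial(n_mut, 0.5) - n_mut
            else:
                steps = np.zeros(n, dtype=int)
            alleles[survived] = np.maximum(founder_allele + steps[survived], 1)
            n_lost = int((~survived).sum())
            if n_lost:
                alleles[~survived] = _draw(rng, config.control_freqs[marker.name], n_lost)
            carrier_alleles[marker.name] = alleles
    for i in range(n):
        records.append(
            ChromosomeRecord(
                chrom_id=f"carrier_{i + 1:04d}",
                family_id=f"fam_{i + 1:04d}",
                group="carrier",
                independent=True,
                alleles={name: int(carrier_alleles[name][i]) for name in names},
            )
        )

    control_alleles = {
        name: _draw(rng, config.control_freqs[name], config.n_controls) for name in names
    }
    for i in range(config.n_controls):
        records.append(
            ChromosomeRecord(
                chrom_id=f"control_{i + 1:04d}",
                family_id=f"ctl_{i + 1:04d}",
                group="control",
                independent=True,
                alleles={name: int(control_alleles[name][i]) for name in names},
            )
        )
    return HaplotypeSet(config.map, tuple(records))


def _draw(rng: np.random.Generator, freqs: Mapping[int, float], size: int) -> np.ndarray:
    alleles = np.array(sorted(freqs))
    probs = np.array([freqs[a] for a in alleles])
    return rng.choice(alleles, size=size, p=probs / probs.sum())


ESTIMATORS = ("risch", "markov", "mrca_mle", "bayes")


def _estimate(
    estimator: str, hapset: HaplotypeSet, anc: AncestralHaplotype
) -> tuple[float, Optional[tuple[float, float]]]:
    if estimator == "risch":
        est = moment_pipeline(hapset, anc, method="risch")
        return est.g_point, None
    if estimator == "markov":
        est = moment_pipeline(hapset, anc, method="markov")
        return est.g_point, None
    if estimator == "mrca_mle":
        res = mrca_mle(hapset, anc)
        return float(res.g_hat), (float(res.ci95[0]), float(res.ci95[1]))
    if estimator == "bayes":
        post = bayes_posterior(hapset, anc, config=BayesConfig(prior="uniform"))
        return float(post.mode), (float(post.credible95[0]), float(post.credible95[1]))
    raise ValueError(f"unknown estimator {estimator!r}")


def recovery_experiment(
    configs: Sequence[SimulationConfig],
    estimators: Sequence[str],
    n_replicates: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Simulate -> estimate -> score, for each config x estimator x replicate.

    The ancestral haplotype handed to the estimators is the generator's
    founder (truth), so the experiment scores estimator error in isolation.
    Estimator failures on a replicate are recorded as NaN, not fatal.
    Returns (per-replicate table, summary table); the summary (bias, RMSE,
    interval coverage, failure rate) is None when n_replicates < 2.
    """
    for est in estimators:
        if est not in ESTIMATORS:
            raise ValueError(f"unknown estimator {est!r}")
    ss = np.random.SeedSequence(seed)
    rows = []
    for config in configs:
        anc = AncestralHaplotype(
            {name: frozenset({config.founder[name]}) for name in config.map.names}
        )
        child_seeds = ss.spawn(n_replicates)
        for rep in range(n_replicates):
            rep_seed = int(child_seeds[rep].generate_state(1)[0] % (2**31))
            hapset = simulate(replace(config, seed=rep_seed))
            for est in estimators:
                row = {
                    "g_true": config.g_true,
                    "estimator": est,
                    "replicate": rep,
                    "seed": rep_seed,
                }
                try:
                    import warnings as _w

                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        point, interval = _estimate(est, hapset, anc)
                    row["g_hat"] = point
                    row["ci_low"] = interval[0] if interval else np.nan
                    row["ci_high"] = interval[1] if interval else np.nan
                    row["failed"] = False
                except Exception:
                    row["g_hat"] = np.nan
                    row["ci_low"] = np.nan
                    row["ci_high"] = np.nan
                    row["failed"] = True
                rows.append(row)
    table = pd.DataFrame(rows)
    if n_replicates < 2:
        return table, None
    summaries = []
    for (g_true, est), grp in table.groupby(["g_true", "estimator"]):
        ok = grp[~grp["failed"]]
        err = ok["g_hat"] - g_true
        has_ci = ok.dropna(subset=["ci_low", "ci_high"])
        coverage = (
            float(((has_ci["ci_low"] <= g_true) & (g_true <= has_ci["ci_high"])).mean())
            if len(has_ci)
            else np.nan
        )
        summaries.append(
            {
                "g_true": g_true,
                "estimator": est,
                "n_ok": len(ok),
                "bias": float(err.mean()) if len(ok) else np.nan,
                "median_g": float(ok["g_hat"].median()) if len(ok) else np.nan,
                "median_abs_error": float(err.abs().median()) if len(ok) else np.nan,
                "rmse": float(np.sqrt((err**2).mean())) if len(ok) else np.nan,
                "coverage95": coverage,
                "failure_rate": float(grp["failed"].mean()),
            }
        )
    return table, pd.DataFrame(summaries)
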