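"""Simulation studies of the toolbox's operating characteristics.

These routines re-run the full analysis pipelines on freshly generated
synthetic data to measure calibration (type-I error of the cumulative
Mann-Kendall test under the null), power (detection of an injected
lysine composition shift), parameter recovery (property slope), and
ranking behaviour of the substitution-bias scan.  They back both the
test suite and the reproduction script.

Study conditions follow the package-wide defaults of
:class:`~protadapt.simulate.FixtureSpec` (6 sequences from 3 ordered
groups per family, 150 sites); per-study family counts are stated per
function.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np

from . import composition, properties, simulate, substitutions


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def null_rejection_rate(
    n_sims: int = 1000,
    seed: int = 0,
    n_families: int = 50,
    alpha: float = 0.05,
    feature: str = "K",
) -> float:
    """Fraction of null data sets (no injected signal) in which the
    composition cumulative Mann-Kendall test rejects at ``alpha``."""
    seeds = _spawn_seeds(seed, n_sims)
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            alns = simulate.generate(
                simulate.FixtureSpec(n_families=n_families, seed=int(s))
            )
            res = composition.composition_trend(alns, feature, "cumulative_mk")
            rejections += res.p_two_sided < alpha
    return rejections / n_sims


def composition_power(
    n_sims: int = 200,
    seed: int = 0,
    n_families: int = 30,
    shift: float = 0.05,
    alpha: float = 0.05,
    feature: str = "K",
) -> float:
    """Detection rate of a per-group-step composition shift in one
    residue by the cumulative Mann-Kendall test."""
    seeds = _spawn_seeds(seed, n_sims)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            alns = simulate.generate(
                simulate.FixtureSpec(
                    n_families=n_families,
                    composition_shift={feature: shift},
                    seed=int(s),
                )
            )
            res = composition.composition_trend(alns, feature, "cumulative_mk")
            hits += res.p_two_sided < alpha
    return hits / n_sims


def slope_recovery(
    seed: int = 0,
    n_families: int = 65,
    beta1: float = 0.05,
    scale_name: str = "kd_hydrophobicity",
) -> Tuple[float, float]:
    """(mean estimated slope, standard error) across families generated
    with an injected per-group-step property slope."""
    spec = simulate.FixtureSpec(
        n_families=n_families,
        property_slope=(scale_name, beta1, 0.0),
        seed=seed,
    )
    alns = simulate.generate(spec)
    scale = properties.get_scale(scale_name)
    slopes = [s.beta1 for s in properties.family_slopes(alns, scale)]
    return float(np.mean(slopes)), float(np.std(slopes, ddof=1) / np.sqrt(len(slopes)))


def substitution_top_rank_rate(
    n_sims: int = 100,
    seed: int = 0,
    n_families: int = 65,
    multiplier: float = 3.0,
    top_k: int = 3,
    pair: Tuple[str, str] = ("K", "R"),
) -> float:
    """Fraction of simulations in which the injected directional bias
    lands among the ``top_k`` smallest p-values of the full scan."""
    seeds = _spawn_seeds(seed, n_sims)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            alns = simulate.generate(
                simulate.FixtureSpec(
                    n_families=n_families,
                    substitution_bias=(pair[0], pair[1], multiplier),
                    seed=int(s),
                )
            )
            fwd = substitutions.sp_matrix(alns, 1, 3)
            bkg = substitutions.sp_matrix(alns, 1, 1, "symmetric_within")
            scan = substitutions.scan_substitution_bias(fwd, bkg)
            top = scan.nsmallest(top_k, "p")
            hits += any((r.x, r.y) == pair for r in top.itertuples())
    return hits / n_sims
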