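"""Reproducible experiment drivers: deviation profiles, quartet series, and
tree-scale reconstruction series.

Each driver takes explicit parameters, seeds a single generator, and returns
a tidy :class:`pandas.DataFrame` (one row per grid point and SR function)
whose ``attrs`` carry the configuration and seed.  The command-line interface
in :mod:`phylosr.cli` is a thin wrapper writing these tables as TSV.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .additivity import Interval, deviation_from_additivity, linear_interpolation
from .errors import InvalidInputError
from .noise import sigma_affine, sigma_jc, sigma_k2p
from .quartets import (QuartetModel, fisher_criterion, quartet_accuracy_multi,
                       sep_noise_ratios)
from .sr import JC, SRFunction, get_sr_function
from .trees import scale_tree_to_diameter, simulated_rf_multi

logger = logging.getLogger(__name__)

__all__ = [
    "run_deviation_profile",
    "run_quartet_series",
    "run_tree_series",
    "crossing_points",
    "fitted_crossing",
]


def run_deviation_profile(R: float, interval, k: int = 500,
                          n_points: int = 201) -> pd.DataFrame:
    """Profile of the JC distance against its best affine surrogate.

    Emits, over a time grid on the interval: the JC curve, its linear
    interpolation, the minimax affine surrogate (interpolation shifted by
    half the maximal gap), and +-1 SD stochastic margins for both the JC
    estimator and the surrogate (whose noise is the Kimura-estimator noise
    scaled by the slope).
    """
    iv = interval if isinstance(interval, Interval) else Interval(*interval)
    result = deviation_from_additivity(JC, R, iv)
    interp = linear_interpolation(JC, R, iv)
    ts = np.linspace(iv.t0, iv.t1, n_points)
    jc_vals = JC.from_time(R, ts)
    star_vals = result.fit(ts)
    sd_jc = np.array([sigma_jc(R, t, k).sd for t in ts])
    sd_star = np.array([sigma_affine(result.fit, sigma_k2p(R, t, k)).sd for t in ts])
    df = pd.DataFrame({
        "t": ts,
        "delta_jc": jc_vals,
        "delta_int": interp(ts),
        "delta_star": star_vals,
        "sd_jc": sd_jc,
        "sd_star": sd_star,
    })
    df.attrs.update({
        "R": R, "t0": iv.t0, "t1": iv.t1, "k": k,
        "A": interp.a, "B": interp.b,
        "a_star": result.fit.a, "b_star": result.fit.b,
        "dev": result.dev, "argmax_t": result.argmax_t, "method": result.method,
    })
    return df


def _resolve_sr(names) -> list[SRFunction]:
    return [get_sr_function(n) if isinstance(n, str) else n for n in names]


def run_quartet_series(qtype: str, R: float, t_i: float, t_l: float,
                       ts_values, k: int, reps: int, sr_functions=("jc", "k2p"),
                       seed: int | None = None,
                       tl_values=None) -> pd.DataFrame:
    """Accuracy, FC, and SEP/NOISE ratios along a quartet series.

    Either ``ts_values`` varies at fixed ``t_l`` (pass ``tl_values=None``) or
    ``tl_values`` varies at fixed ``t_s`` (pass the fixed short length via
    ``ts_values`` as a scalar).  ``reps=0`` skips the Monte-Carlo accuracy
    and emits only the deterministic FC columns.
    """
    srs = _resolve_sr(sr_functions)
    rng = np.random.default_rng(seed)
    rows = []
    if tl_values is None:
        grid = [(float(ts), float(t_l)) for ts in np.atleast_1d(ts_values)]
    else:
        ts_fixed = float(np.atleast_1d(ts_values)[0])
        grid = [(ts_fixed, float(tl)) for tl in np.atleast_1d(tl_values)]
    for ts, tl in grid:
        q = QuartetModel(qtype, t_i, ts, tl, R)
        row_base = {"t_s": ts, "t_l": tl, "ratio": tl / ts}
        fcs = {}
        acc = {}
        if reps > 0:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            acc = quartet_accuracy_multi(q, srs, k, reps, seed=sub_seed)
        for sr in srs:
            row = dict(row_base)
            row["sr"] = sr.name
            try:
                fc = fisher_criterion(q, sr, k)
                row["fc"] = fc.fc
                row["sep"] = fc.sep
                row["noise"] = fc.noise
                fcs[sr.name] = fc
            except InvalidInputError:
                row["fc"] = np.nan
                row["sep"] = np.nan
                row["noise"] = np.nan
            if reps > 0:
                row["accuracy"] = acc[sr.name]
            rows.append(row)
        if len(srs) == 2 and len(fcs) == 2:
            sep_r, noise_r, fc_r = sep_noise_ratios(q, srs[0], srs[1], k)
            for row in rows[-2:]:
                row["sep_ratio"] = sep_r
                row["noise_ratio"] = noise_r
                row["fc_ratio"] = fc_r
    df = pd.DataFrame(rows)
    df.attrs.update({"qtype": qtype, "R": R, "t_i": t_i, "k": k,
                     "reps": reps, "seed": seed,
                     "sr": [s.name for s in srs]})
    return df


def run_tree_series(tree, R: float, k: int, scales, reps: int,
                    sr_functions=("jc", "k2p", "tv"),
                    seed: int | None = None) -> pd.DataFrame:
    """Mean normalized RF of NJ reconstruction across tree-diameter scales.

    For each target diameter the tree is rescaled, ``reps`` alignments are
    simulated under K2P(R), and each SR function's distance matrix is fed to
    neighbor joining; the table reports the mean normalized RF to the true
    topology per (scale, SR function).
    """
    srs = _resolve_sr(sr_functions)
    rng = np.random.default_rng(seed)
    rows = []
    for s in np.atleast_1d(scales):
        scaled = scale_tree_to_diameter(tree, float(s))
        sub_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        rf_by_sr = simulated_rf_multi(scaled, srs, R, k, reps, sub_rng)
        for sr in srs:
            rf = rf_by_sr[sr.name]
            rows.append({"scale": float(s), "sr": sr.name,
                         "mean_rf": float(rf.mean()),
                         "se_rf": float(rf.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0})
    df = pd.DataFrame(rows)
    df.attrs.update({"R": R, "k": k, "reps": reps, "seed": seed,
                     "sr": [s.name for s in srs]})
    return df


def fitted_crossing(x, diff, deg: int = 3) -> float:
    """Zero crossing of a noisy sampled difference curve.

    Fits a least-squares polynomial to ``diff`` over ``x`` and returns the
    real root inside the sampled range; with several such roots, the one
    nearest the raw sign change is taken.  More stable than pointwise
    interpolation when the per-point values carry Monte-Carlo noise.
    """
    x = np.asarray(x, dtype=float)
    diff = np.asarray(diff, dtype=float)
    ok = np.isfinite(diff)
    x, diff = x[ok], diff[ok]
    coeffs = np.polyfit(x, diff, deg)
    roots = np.roots(coeffs)
    real = [float(r.real) for r in roots
            if abs(r.imag) < 1e-9 and x.min() <= r.real <= x.max()]
    if not real:
        raise InvalidInputError("no zero crossing inside the sampled range")
    raw = crossing_points(x, diff)
    anchor = raw[0] if raw else float(x[np.argmin(np.abs(diff))])
    return min(real, key=lambda r: abs(r - anchor))


def crossing_points(x: np.ndarray, diff: np.ndarray) -> list[float]:
    """x-locations where a sampled curve changes sign, by linear
    interpolation between adjacent grid points (ignoring exact zeros at
    isolated points)."""
    x = np.asarray(x, dtype=float)
    diff = np.asarray(diff, dtype=float)
    order = np.argsort(x)
    x, diff = x[order], diff[order]
    out = []
    for i in range(len(x) - 1):
        d0, d1 = diff[i], diff[i + 1]
        if np.isnan(d0) or np.isnan(d1):
            continue
        if d0 == 0.0:
            out.append(float(x[i]))
        elif np.sign(d0) != np.sign(d1) and d1 != 0.0:
            out.append(float(x[i] + (x[i + 1] - x[i]) * (-d0) / (d1 - d0)))
    return out
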