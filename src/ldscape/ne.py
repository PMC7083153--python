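"""LD-based effective population size history.

The expected squared allele-state correlation between two loci at
recombination fraction ``c`` in a closed random-mating population of
effective size ``Ne`` follows the Sved relationship

    E[r^2] = 1 / (alpha + 4 Ne c) + 1/(2n),

where ``alpha`` is 1 (monogamous / no mutation correction) or 2 and the
``1/(2n)`` term is the sampling inflation for ``n`` diploids.  LD at
recombination fraction ``c`` reflects the population roughly
``t = 1/(2c)`` generations ago, so binning observed pairs by distance
and inverting the relationship per bin traces an Ne trajectory through
time.  Physical distance maps to ``c`` through a uniform genetic map
(default 1 cM/Mb).

:class:`SvedNeModel` wraps the procedure as a model object whose
``fit()`` returns an :class:`NeResults` carrying the trajectory, the
present-day log-log regression extrapolation, and a ``summary()``
table; the module-level functions are thin functional equivalents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class NeConfig:
    """Tunables of the LD -> Ne inversion.

    cm_per_mb : uniform genetic-map density (cM per Mb, default 1.0).
    generations : target generations ago at which Ne is estimated.
    alpha : mating-system constant of the Sved form (1 or 2).
    sample_correction : subtract 1/(2n) from mean r2 before inverting.
    window_frac : pairs are pooled whose c lies within this relative
        window of the target 1/(2t).
    min_pairs : below this pair count an estimate is flagged low-confidence.
    """

    cm_per_mb: float = 1.0
    generations: tuple[int, ...] = (200, 100, 50, 10, 5)
    alpha: int = 1
    sample_correction: bool = True
    window_frac: float = 0.2
    min_pairs: int = 10

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be > 0")
        if any(t <= 0 for t in self.generations):
            raise ValueError("generations must be positive")
        if self.alpha not in (1, 2):
            raise ValueError("alpha must be 1 or 2")


def morgans_per_bp(cfg: NeConfig) -> float:
    """Morgans per base pair under the uniform map (1 cM/Mb -> 1e-8)."""
    return cfg.cm_per_mb / 100.0 / 1e6


def distance_for_generation(t: float, cfg: NeConfig | None = None) -> tuple[float, float]:
    """Recombination fraction and physical window probing ``t`` generations ago.

    Returns ``(c, bp)`` with ``c = 1/(2t)`` Morgans and ``bp`` the
    physical distance whose expected genetic length is ``c`` at the
    configured map density.  ``t`` must exceed 1 so that ``c < 0.5``.
    """
    cfg = cfg or NeConfig()
    if t <= 0:
        raise ValueError("t must be > 0")
    c = 1.0 / (2.0 * t)
    if c >= 0.5:
        raise ValueError(f"t={t} gives c={c} >= 0.5; need t > 1")
    return c, c / morgans_per_bp(cfg)


def estimate_ne(
    pairs: pd.DataFrame, n_samples: int, cfg: NeConfig | None = None
) -> pd.DataFrame:
    """Ne trajectory from per-pair LD (columns ``distance`` bp and ``r2``).

    For each target generation t: pairs whose recombination fraction c
    lies within ±window_frac of 1/(2t) are pooled; mean r2 is corrected
    by -1/(2n) when configured; and

        Ne = (1 / (4 c_mean)) * (1 / mean_r2_adj - alpha).

    Returns one row per t with columns t, c_target, c_mean, n_pairs,
    mean_r2, mean_r2_adj, ne (rounded to integer; NaN when the adjusted
    mean is <= 0) and flag ("" | "low_confidence" | "unavailable").
    """
    cfg = cfg or NeConfig()
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    c_all = pairs["distance"].to_numpy(dtype=float) * morgans_per_bp(cfg)
    c_all = np.minimum(c_all, 0.5)
    r2_all = pairs["r2"].to_numpy(dtype=float)
    correction = 1.0 / (2.0 * n_samples) if cfg.sample_correction else 0.0
    rows = []
    for t in cfg.generations:
        c0, _ = distance_for_generation(t, cfg)
        sel = np.abs(c_all - c0) <= cfg.window_frac * c0
        n_used = int(sel.sum())
        mean_r2 = float(r2_all[sel].mean()) if n_used else np.nan
        mean_adj = mean_r2 - correction if n_used else np.nan
        flag = ""
        ne = np.nan
        if n_used == 0 or not np.isfinite(mean_adj) or mean_adj <= 0:
            flag = "unavailable"
        else:
            c_mean = float(c_all[sel].mean())
            ne = round((1.0 / (4.0 * c_mean)) * (1.0 / mean_adj - cfg.alpha))
            if ne <= 0:
                ne, flag = np.nan, "unavailable"
            elif n_used < cfg.min_pairs:
                flag = "low_confidence"
        rows.append(
            {
                "t": t,
                "c_target": c0,
                "c_mean": float(c_all[sel].mean()) if n_used else np.nan,
                "n_pairs": n_used,
                "mean_r2": mean_r2,
                "mean_r2_adj": mean_adj,
                "ne": ne,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def extrapolate_present(traj: pd.DataFrame) -> tuple[int, float, float]:
    """Present-day Ne by ordinary least squares of log(Ne) on log(t).

    Needs at least three valid (positive-Ne) trajectory points; returns
    ``(ne_at_t1, slope, intercept)`` with the regression evaluated at
    t = 1 and rounded to an integer.
    """
    ok = traj.dropna(subset=["ne"])
    ok = ok[ok["ne"] > 0]
    if len(ok) < 3:
        raise ValueError(f"need >= 3 valid Ne estimates, got {len(ok)}")
    x = np.log(ok["t"].to_numpy(dtype=float))
    y = np.log(ok["ne"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    return int(round(float(np.exp(intercept)))), float(slope), float(intercept)


def sved_expected_r2(c: np.ndarray, ne: float, alpha: int = 1,
                     n_samples: int | None = None) -> np.ndarray:
    """Expected r2 under the Sved form, optionally with the 1/(2n) term."""
    r2 = 1.0 / (alpha + 4.0 * ne * np.asarray(c, dtype=float))
    if n_samples:
        r2 = r2 + 1.0 / (2.0 * n_samples)
    return r2


class SvedNeModel:
    """Effective-population-size model over observed pairwise LD.

    Parameters
    ----------
    pairs : DataFrame with per-pair ``distance`` (bp) and ``r2``
        (typically the output of :func:`ldscape.ld.compute_pair_ld`).
    n_samples : number of diploids behind the r2 estimates.
    config : :class:`NeConfig`, optional.
    """

    def __init__(self, pairs: pd.DataFrame, n_samples: int,
                 config: NeConfig | None = None):
        for col in ("distance", "r2"):
            if col not in pairs.columns:
                raise ValueError(f"pairs is missing column {col!r}")
        self.pairs = pairs
        self.n_samples = int(n_samples)
        self.config = config or NeConfig()

    @classmethod
    def from_genotypes(cls, gm, config: NeConfig | None = None,
                       max_dist: int | None = None) -> "SvedNeModel":
        """Build directly from a scaffold-filtered :class:`GenotypeMatrix`."""
        from .ld import compute_pair_ld

        config = config or NeConfig()
        if max_dist is None:
            # widest window needed: the smallest t probes the largest c
            _, bp = distance_for_generation(min(config.generations), config)
            max_dist = int(bp * (1 + config.window_frac)) + 1
        pairs = compute_pair_ld(gm, max_dist=max_dist)
        return cls(pairs, n_samples=gm.n_samples, config=config)

    def fit(self) -> "NeResults":
        traj = estimate_ne(self.pairs, self.n_samples, self.config)
        try:
            ne_now, slope, intercept = extrapolate_present(traj)
        except ValueError as err:
            log.warning("present-day extrapolation unavailable: %s", err)
            ne_now, slope, intercept = None, np.nan, np.nan
        return NeResults(model=self, trajectory=traj, ne_present=ne_now,
                         slope=slope, intercept=intercept)


@dataclass
class NeResults:
    """Fitted Ne trajectory with present-day extrapolation."""

    model: SvedNeModel
    trajectory: pd.DataFrame
    ne_present: int | None
    slope: float
    intercept: float

    def predict_r2(self, distance_bp: np.ndarray, t: float) -> np.ndarray:
        """Expected r2 at given distances were Ne fixed at the t-generations
        estimate (diagnostic back-prediction)."""
        row = self.trajectory[self.trajectory["t"] == t]
        if row.empty or not np.isfinite(row["ne"].iloc[0]):
            raise ValueError(f"no Ne estimate at t={t}")
        c = np.asarray(distance_bp, dtype=float) * morgans_per_bp(self.model.config)
        return sved_expected_r2(c, float(row["ne"].iloc[0]),
                                self.model.config.alpha, self.model.n_samples)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "LD-based effective population size (Sved inversion)",
            "=" * 55,
            f"pairs: {len(self.model.pairs)}   diploids: {self.model.n_samples}",
            f"alpha={cfg.alpha}  map={cfg.cm_per_mb} cM/Mb  "
            f"sample correction={'1/(2n)' if cfg.sample_correction else 'off'}",
            "",
            self.trajectory.to_string(
                index=False,
                formatters={
                    "c_target": "{:.5f}".format,
                    "c_mean": "{:.5f}".format,
                    "mean_r2": "{:.4f}".format,
                    "mean_r2_adj": "{:.4f}".format,
                },
            ),
            "",
        ]
        if self.ne_present is not None:
            lines.append(
                f"present-day Ne (log-log OLS at t=1): {self.ne_present}  "
                f"[slope={self.slope:.3f}]"
            )
        else:
            lines.append("present-day Ne: unavailable (<3 valid estimates)")
        return "\n".join(lines)
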