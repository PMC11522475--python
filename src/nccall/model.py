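"""Bayesian N/C scoring of dual-epitope chromatin profiling signal.

For each genomic interval the base pairs of N-terminal and C-terminal
antibody signal are treated as counts from two multinomial distributions over
the shared interval universe. With a uniform (add-one) Dirichlet prior, the
posterior over each terminus' interval fractions is Dirichlet(counts + 1).
The N/C score of interval *i* is

    r_NC(i) = log2(p_N(i) / p_C(i)),

summarized by Monte-Carlo sampling: ``n_draws`` posterior simplex draws per
terminus give a mean ``mu`` and standard deviation ``sd`` per interval, a
z-score ``mu/sd``, and a normal-tail p-value, BH-corrected across intervals.
Intervals with ``mu`` above a magnitude threshold and p below a significance
threshold are called oncoprotein target sites, and every interval receives an
oncoprotein score ``mu * -log10(p + pseudo)`` combining magnitude and
significance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

__all__ = [
    "ModelConfig",
    "posterior_nc_scores",
    "bh_adjust",
    "oncoprotein_score",
    "call_target_sites",
    "average_oncoprotein_score",
    "score_sample",
    "substream",
]

SCORE_COLUMNS = [
    "interval_id", "bp_n", "bp_c", "mu", "sd", "z", "p_raw", "q_bh",
    "onco_score", "called",
]


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the N/C posterior model and site calling.

    Defaults are the published operating point: 1000 Monte-Carlo draws,
    add-one Dirichlet prior, N/C score threshold 1.75, p threshold 1e-5,
    and a 1e-10 pseudo count inside the -log10 of the oncoprotein score.
    """

    n_draws: int = 1000
    seed: int = 0
    prior_pseudocount: float = 1.0
    nc_threshold: float = 1.75
    p_threshold: float = 1e-5
    log_pseudo: float = 1e-10
    p_sidedness: str = "one-sided-upper"  # or "two-sided"
    p_for_calling: str = "bh"  # or "raw"

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if min(self.nc_threshold, self.p_threshold, self.log_pseudo) <= 0:
            raise ValueError("thresholds must be positive")
        if self.p_sidedness not in ("one-sided-upper", "two-sided"):
            raise ValueError(f"unknown p_sidedness {self.p_sidedness!r}")
        if self.p_for_calling not in ("bh", "raw"):
            raise ValueError(f"unknown p_for_calling {self.p_for_calling!r}")


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Deterministic named RNG substream derived from a base seed.

    Stream identity is (seed, names...) with names hashed stably (CRC-32),
    so e.g. the N- and C-terminal draws of one sample never share a stream.
    """
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *keys]))


def posterior_nc_scores(
    counts: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    sample_id: str = "",
) -> pd.DataFrame:
    """Monte-Carlo posterior summary of the per-interval N/C log-ratio.

    ``counts`` needs columns interval_id, bp_n, bp_c (non-negative). Returns
    a DataFrame with mu, sd, z, p_raw and q_bh per interval, in input order.
    Draws for the two termini use independent RNG substreams derived from
    (config.seed, sample_id, terminus), so results are reproducible.
    """
    if len(counts) < 2:
        raise ValueError("posterior_nc_scores: need >=2 intervals (simplex is degenerate)")
    bp_n = counts["bp_n"].to_numpy(dtype=float)
    bp_c = counts["bp_c"].to_numpy(dtype=float)
    if not (np.isfinite(bp_n).all() and np.isfinite(bp_c).all()):
        raise ValueError("posterior_nc_scores: non-finite counts")
    if (bp_n < 0).any() or (bp_c < 0).any():
        raise ValueError("posterior_nc_scores: negative counts")

    rng_n = substream(config.seed, sample_id, "N")
    rng_c = substream(config.seed, sample_id, "C")
    alpha_n = bp_n + config.prior_pseudocount
    alpha_c = bp_c + config.prior_pseudocount
    p_n = rng_n.dirichlet(alpha_n, size=config.n_draws)
    p_c = rng_c.dirichlet(alpha_c, size=config.n_draws)
    # dirichlet draws can underflow to exactly 0 for small alpha; floor them
    tiny = np.finfo(float).tiny
    r = np.log2(np.maximum(p_n, tiny)) - np.log2(np.maximum(p_c, tiny))

    mu = r.mean(axis=0)
    sd = r.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mu / sd, 0.0)
    if config.p_sidedness == "one-sided-upper":
        p_raw = stats.norm.sf(z)
    else:
        p_raw = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = sd == 0
    p_raw = np.where(degenerate, 1.0, p_raw)

    out = pd.DataFrame(
        {
            "interval_id": counts["interval_id"].to_numpy(),
            "bp_n": counts["bp_n"].to_numpy(),
            "bp_c": counts["bp_c"].to_numpy(),
            "mu": mu,
            "sd": sd,
            "z": z,
            "p_raw": p_raw,
            "degenerate_sd": degenerate,
        }
    )
    out["q_bh"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    _, q = fdrcorrection(p, alpha=0.05, method="indep", is_sorted=False)
    return q


def oncoprotein_score(
    mu: np.ndarray | float, p: np.ndarray | float, log_pseudo: float = 1e-10
) -> np.ndarray | float:
    """Magnitude-times-significance score: ``mu * -log10(p + log_pseudo)``.

    The pseudo count inside the log keeps p = 0 finite (score bounded by
    ``mu * -log10(log_pseudo)``).
    """
    return mu * (-np.log10(np.asarray(p, dtype=float) + log_pseudo))


def call_target_sites(scores: pd.DataFrame, config: ModelConfig = ModelConfig()) -> pd.DataFrame:
    """Flag oncoprotein target sites and fill oncoprotein scores.

    A site is called when mu strictly exceeds ``nc_threshold`` and the
    configured p-value (BH-adjusted by default) is strictly below
    ``p_threshold``. The oncoprotein score is computed for every interval,
    called or not.
    """
    out = scores.copy()
    p_star = out["q_bh"] if config.p_for_calling == "bh" else out["p_raw"]
    p_star = p_star.to_numpy(dtype=float)
    out["onco_score"] = oncoprotein_score(out["mu"].to_numpy(), p_star, config.log_pseudo)
    out["called"] = (out["mu"].to_numpy() > config.nc_threshold) & (p_star < config.p_threshold)
    return out


def average_oncoprotein_score(scores: pd.DataFrame) -> float:
    """Mean oncoprotein score over the full combined site universe."""
    if len(scores) == 0:
        raise ValueError("average_oncoprotein_score: empty site universe")
    return float(scores["onco_score"].mean())


def score_sample(
    counts: pd.DataFrame, config: ModelConfig = ModelConfig(), sample_id: str = ""
) -> pd.DataFrame:
    """Posterior scoring plus calling in one step (per-sample convenience)."""
    return call_target_sites(posterior_nc_scores(counts, config, sample_id), config)
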