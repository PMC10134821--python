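"""Rejection approximate Bayesian computation for leakage and diffusion.

The coculture model's free parameters — the membrane diffusion rate d and
the amino-acid leakage stoichiometries e — are inferred likelihood-free:
draw parameter vectors from the prior, simulate the positive-control and
membrane-separated experiments, compute the log10 growth-ratio statistic
S, and accept the draw when S falls within k observed standard deviations
of the observed mean,

    accept  iff  |S_sim - m_obs| <= k * sd_obs,

for the per-strain variant the condition must hold for BOTH strains
simultaneously.  Three shipped presets mirror the study configurations:
``equal`` (one shared leakage, d free), ``unequal`` (d fixed, independent
leakages per amino acid, per-strain acceptance) and ``noisy`` (``equal``
with one-decade log-uniform priors on every literature-estimated kinetic
parameter).  The observed means/sds are config inputs — they come from
wet-lab growth curves and are not recomputed here.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .coculture import D_DEFAULT, default_strains, paired_statistic

#: strain-level kinetic parameters that the noisy preset opens to priors
KINETIC_PARAMS = ("vmax_glc", "km_glc", "vmax_aa", "km_aa", "y_glc")


@dataclass(frozen=True)
class PriorSpec:
    """One parameter's prior: log-uniform over [low, high], or a point mass."""

    name: str
    kind: str  # {"log_uniform", "point"}
    low: float
    high: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("log_uniform", "point"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "log_uniform":
            if self.low <= 0:
                raise ValueError("log-uniform bounds must be positive")
            if self.high is None or self.low >= self.high:
                raise ValueError("log-uniform needs low < high")

    @classmethod
    def log_uniform_centered(
        cls, name: str, center: float, decades: float = 1.0
    ) -> "PriorSpec":
        """Log-uniform prior spanning ``decades`` orders of magnitude
        centered (in log10 space) on ``center``."""
        if center <= 0 or decades <= 0:
            raise ValueError("center and decades must be positive")
        half = 10.0 ** (decades / 2.0)
        return cls(name=name, kind="log_uniform", low=center / half, high=center * half)

    @classmethod
    def point(cls, name: str, value: float) -> "PriorSpec":
        return cls(name=name, kind="point", low=value)

    def log10_bounds(self) -> tuple[float, float]:
        if self.kind == "point":
            return (math.log10(self.low),) * 2
        return math.log10(self.low), math.log10(self.high)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.low)
        lo, hi = self.log10_bounds()
        return 10.0 ** rng.uniform(lo, hi, size=n)

    @property
    def is_free(self) -> bool:
        return self.kind != "point"


@dataclass
class ABCConfig:
    """Everything one rejection run needs, including its seed.

    ``observed_mean``/``observed_sd`` are floats in mean mode, or dicts
    keyed by strain name in per-strain mode; ``k`` is the acceptance
    half-width in units of the observed standard deviation.
    """

    priors: list[PriorSpec]
    n_samples: int
    observed_mean: float | dict[str, float]
    observed_sd: float | dict[str, float]
    k: float
    statistic_mode: str = "mean"
    t_statistic: float = 48.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.statistic_mode not in ("mean", "per_strain"):
            raise ValueError("statistic_mode must be 'mean' or 'per_strain'")
        sds = (
            self.observed_sd.values()
            if isinstance(self.observed_sd, dict)
            else [self.observed_sd]
        )
        if any(s <= 0 for s in sds):
            raise ValueError("observed sd must be positive")

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.priors]

    @property
    def free_params(self) -> list[str]:
        return [p.name for p in self.priors if p.is_free]


@dataclass
class Posterior:
    """All prior draws with their statistics and acceptance flags.

    ``prior_draws`` keeps every draw (for heat-map style parameter-space
    plots); ``draws`` is the accepted subset.  Draws whose simulation
    failed are recorded with an ``error`` string and counted as rejected,
    never dropped.
    """

    prior_draws: pd.DataFrame
    config: ABCConfig

    @property
    def draws(self) -> pd.DataFrame:
        return self.prior_draws[self.prior_draws["accepted"]]

    @property
    def acceptance_rate(self) -> float:
        return float(self.prior_draws["accepted"].mean())


def sample_prior(config: ABCConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ``n_samples`` parameter vectors; one column per prior, in
    prior order.  Reproducible given ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return pd.DataFrame(
        {p.name: p.sample(rng, config.n_samples) for p in config.priors}
    )


def make_model_hook(
    statistic_mode: str = "mean",
    t: float = 48.0,
    d_default: float = D_DEFAULT,
    max_step: float | None = None,
    **solver_opts,
):
    """Build the simulate-and-summarise callable the rejection loop uses.

    The returned hook maps a parameter dict (``d``, ``e_leak`` or
    ``e_lys``/``e_ile``, plus optional kinetic overrides) to the growth
    statistic.  The inner loop integrates with free adaptive stepping
    (``max_step=None``), which tracks the capped reference solution to
    well below the acceptance width at a fraction of the cost.
    """

    def hook(params: dict[str, float]):
        e_shared = params.get("e_leak", 1.0)
        dlys, dile = default_strains(
            e_lys=params.get("e_lys", e_shared), e_ile=params.get("e_ile", e_shared)
        )
        overrides = {k: params[k] for k in KINETIC_PARAMS if k in params}
        if overrides:
            dlys = dataclasses.replace(dlys, **overrides)
            dile = dataclasses.replace(dile, **overrides)
        return paired_statistic(
            (dlys, dile),
            d=params.get("d", d_default),
            t=t,
            mode=statistic_mode,
            max_step=max_step,
            **solver_opts,
        )

    return hook


def _accepts(config: ABCConfig, stat) -> bool:
    if config.statistic_mode == "mean":
        return abs(stat - config.observed_mean) <= config.k * config.observed_sd
    # per-strain: the window must hold for every strain simultaneously
    return all(
        abs(stat[s] - config.observed_mean[s]) <= config.k * config.observed_sd[s]
        for s in config.observed_mean
    )


def run_rejection(config: ABCConfig, hook=None) -> Posterior:
    """Rejection-ABC: sample the prior, simulate each draw, keep the draws
    whose statistic lands inside the acceptance window."""
    if hook is None:
        hook = make_model_hook(
            statistic_mode=config.statistic_mode, t=config.t_statistic
        )
    draws = sample_prior(config)
    stats_cols: dict[str, list] = {}
    accepted: list[bool] = []
    errors: list[str | None] = []
    for _, row in draws.iterrows():
        params = row.to_dict()
        try:
            stat = hook(params)
        except Exception as exc:  # failed draw: rejected, reason logged
            accepted.append(False)
            errors.append(f"{type(exc).__name__}: {exc}")
            for c in stats_cols:
                stats_cols[c].append(np.nan)
            continue
        if config.statistic_mode == "mean":
            stats_cols.setdefault("S", [np.nan] * len(accepted)).append(stat)
        else:
            for s, v in stat.items():
                stats_cols.setdefault(f"S_{s}", [np.nan] * len(accepted)).append(v)
        accepted.append(_accepts(config, stat))
        errors.append(None)
    out = draws.copy()
    for c, vals in stats_cols.items():
        out[c] = vals
    out["accepted"] = accepted
    out["error"] = pd.array(errors, dtype="string")
    return Posterior(prior_draws=out, config=config)


def posterior_summary(post: Posterior) -> dict:
    """Per-free-parameter log10 median and central 50%/95% intervals, plus
    the acceptance rate.  With zero accepted draws the intervals are NaN."""
    acc = post.draws
    rows = []
    for name in post.config.free_params:
        if len(acc) == 0:
            rows.append(
                {"parameter": name, "median_log10": np.nan,
                 "q25_log10": np.nan, "q75_log10": np.nan,
                 "q2.5_log10": np.nan, "q97.5_log10": np.nan}
            )
            continue
        x = np.log10(acc[name].to_numpy())
        q = np.percentile(x, [50, 25, 75, 2.5, 97.5])
        rows.append(
            {"parameter": name, "median_log10": q[0],
             "q25_log10": q[1], "q75_log10": q[2],
             "q2.5_log10": q[3], "q97.5_log10": q[4]}
        )
    return {
        "acceptance_rate": post.acceptance_rate,
        "n_accepted": int(len(acc)),
        "table": pd.DataFrame(rows).set_index("parameter"),
    }


def heatmap_table(post: Posterior, x: str, y: str) -> pd.DataFrame:
    """(x, y, statistic, accepted) triples over all prior draws, for
    parameter-space maps coloured by S."""
    cols = [c for c in post.prior_draws.columns if c == "S" or c.startswith("S_")]
    return post.prior_draws[[x, y, *cols, "accepted"]].copy()


def _parse_prior(doc: dict) -> PriorSpec:
    kind = doc.get("kind", "log_uniform")
    if kind == "point":
        return PriorSpec.point(doc["name"], float(doc["value"]))
    if "center" in doc:
        return PriorSpec.log_uniform_centered(
            doc["name"], float(doc["center"]), float(doc.get("decades", 1.0))
        )
    return PriorSpec(doc["name"], "log_uniform", float(doc["low"]), float(doc["high"]))


def get_preset(
    name: str, n_samples: int = 500, seed: int = 0
) -> ABCConfig:
    """Load one of the shipped inference presets: equal, unequal or noisy."""
    try:
        text = (
            resources.files("biomesim") / "presets" / f"{name}.yaml"
        ).read_text()
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}") from None
    doc = yaml.safe_load(text)
    obs = doc["observed"]
    return ABCConfig(
        priors=[_parse_prior(p) for p in doc["priors"]],
        n_samples=n_samples,
        observed_mean=obs["mean"],
        observed_sd=obs["sd"],
        k=float(doc["k"]),
        statistic_mode=doc.get("statistic_mode", "mean"),
        t_statistic=float(doc.get("t_statistic", 48.0)),
        seed=seed,
        name=name,
    )
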