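"""Seeded generator of synthetic camera deployments.

The generator stands in for raw deployment data and mirrors the study design
the analysis assumes: 15 adult individuals across two estuarine site/years,
mixed 30-min and 60-min recording intervals totalling ~102 potential hours of
which ~69% are viable, Poisson attack counts with diel-bin rate differences
and lognormal individual heterogeneity, Bernoulli capture outcomes driven by
diel bin and water-column position, and an alternating-renewal (semi-Markov)
activity-bout process reproducing a configured six-category time budget.

All randomness flows from one integer seed, fanned out to named substreams
(``bouts``, ``intercepts``, ``intervals``, ``attacks``) so the bout process
and the attack process are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from scipy.special import expit, logit

from ethoforage._seeds import substream
from ethoforage.ethogram import (
    AttackRecord,
    BehaviorBout,
    BehaviorCategory,
    DielBin,
    SamplingInterval,
    assign_diel_bin,
)


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


_CATEGORIES = tuple(BehaviorCategory)

#: Overall activity time shares used as generator defaults.  The printed
#: six-category budget they are taken from sums to 100.4% because of rounding;
#: weights are renormalized exactly at validation time.
DEFAULT_ACTIVITY_WEIGHTS: Mapping[BehaviorCategory, float] = {
    BehaviorCategory.SIT_SURFACE: 0.414,
    BehaviorCategory.SIT_SUBMERGED: 0.369,
    BehaviorCategory.SWIM_SURFACE: 0.096,
    BehaviorCategory.SWIM_SUBMERGED: 0.059,
    BehaviorCategory.ON_LAND: 0.059,
    BehaviorCategory.FORAGING: 0.007,
}

#: Lognormal bout-duration parameters (mean, sd of log seconds).  The source
#: data report no duration distributions; these give long resting bouts
#: (~10-20 min), shorter swims (~2-3 min) and brief foraging events (~40 s),
#: typical of coded bout data, and are fully configurable.
DEFAULT_DURATION_MODEL: Mapping[BehaviorCategory, tuple[float, float]] = {
    BehaviorCategory.FORAGING: (3.4, 0.7),
    BehaviorCategory.SIT_SURFACE: (6.2, 1.0),
    BehaviorCategory.SIT_SUBMERGED: (6.0, 1.0),
    BehaviorCategory.SWIM_SURFACE: (5.0, 0.8),
    BehaviorCategory.SWIM_SUBMERGED: (4.7, 0.8),
    BehaviorCategory.ON_LAND: (6.5, 1.0),
}

#: Diel multipliers on the attack rate, ordered night > morning > evening >
#: day and chosen so the exposure-weighted mean over the 24-h clock is ~1,
#: keeping the marginal rate at the configured base rate.
DEFAULT_BIN_RATE_MULTIPLIERS: Mapping[DielBin, float] = {
    DielBin.MORNING: 1.1,
    DielBin.DAY: 0.45,
    DielBin.EVENING: 0.7,
    DielBin.NIGHT: 1.9,
}

DEFAULT_SUCCESS_BY_BIN: Mapping[DielBin, float] = {
    DielBin.MORNING: 0.68,
    DielBin.DAY: 0.47,
    DielBin.EVENING: 0.34,
    DielBin.NIGHT: 0.34,
}

DEFAULT_SUCCESS_BY_POSITION: Mapping[str, float] = {
    "submerged": 0.76,
    "surface": 0.41,
}


@dataclass
class SimConfig:
    """Configuration of a synthetic study.

    Defaults reproduce the reference study design: 15 individuals split 9/6
    between the two site/years, 102 potential recording hours on a mixed
    30/60-min interval schedule with a 0.69 viable fraction, a baseline attack
    rate of 0.49 attacks/hour with night-heavy diel multipliers, capture
    success of 0.68/0.47/0.34/0.34 by bin and 0.76/0.41 by water position
    combined additively on the logit scale, and the six-category activity
    budget led by sitting at the surface (41.4%).
    """

    n_individuals: int = 15
    site_split: Optional[tuple[int, int]] = None  # (MINWR_2010, Guana_2011); None = 9:6 ratio
    n_hour_intervals: int = 7  # intervals per 60-min-schedule deployment
    n_half_intervals: int = 13  # intervals per 30-min-schedule deployment
    half_hour_fraction: float = 0.4  # fraction of deployments on the 30-min schedule
    hours_per_deployment: Optional[float] = None  # override the schedule length
    viable_fraction: float = 0.69
    base_attack_rate: float = 0.49  # attacks / hour / individual
    bin_rate_multipliers: Mapping[DielBin, float] = field(
        default_factory=lambda: dict(DEFAULT_BIN_RATE_MULTIPLIERS)
    )
    individual_sd: float = 0.3  # sd of normal random intercepts, log-rate scale
    success_probs_by_bin: Optional[Mapping[DielBin, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUCCESS_BY_BIN)
    )
    success_probs_by_position: Optional[Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUCCESS_BY_POSITION)
    )
    success_anchor: float = 0.53  # reference success level when combining factors
    p_submerged: float = 0.30
    p_sit_and_wait: float = 0.67
    p_vegetation: float = 0.36
    activity_weights: Mapping[BehaviorCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_WEIGHTS)
    )
    activity_weights_by_bin: Optional[Mapping[DielBin, Mapping[BehaviorCategory, float]]] = None
    duration_model: Mapping[BehaviorCategory, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_MODEL)
    )
    #: optional additive shifts to the log-duration mean per (bin, activity);
    #: a nonzero shift makes that cell's bouts atypically long or short — the
    #: kind of diel signal the randomization test is sensitive to
    duration_shift_by_bin: Optional[Mapping[DielBin, Mapping[BehaviorCategory, float]]] = None
    feeding_frenzy: bool = False
    frenzy_count: int = 18

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if sum(self.resolved_site_split()) != self.n_individuals:
            raise ConfigError(
                f"site_split {self.site_split} must sum to n_individuals={self.n_individuals}"
            )
        if not 0.0 <= self.viable_fraction <= 1.0:
            raise ConfigError("viable_fraction must be in [0, 1]")
        if self.base_attack_rate < 0:
            raise ConfigError("base_attack_rate must be >= 0")
        if self.individual_sd < 0:
            raise ConfigError("individual_sd must be >= 0")
        for bin_, m in self.bin_rate_multipliers.items():
            if m < 0:
                raise ConfigError(f"rate multiplier for {bin_} must be >= 0")
        for probs in (
            self.success_probs_by_bin,
            self.success_probs_by_position,
            {"anchor": self.success_anchor},
            {
                "p_submerged": self.p_submerged,
                "p_sit_and_wait": self.p_sit_and_wait,
                "p_vegetation": self.p_vegetation,
            },
        ):
            if probs is None:
                continue
            for key, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"probability for {key} out of [0, 1]: {p}")
        self.normalized_weights()  # raises on bad weights
        if self.activity_weights_by_bin is not None:
            for bin_ in DielBin:
                if bin_ not in self.activity_weights_by_bin:
                    raise ConfigError(f"activity_weights_by_bin missing {bin_}")
                _normalize_weights(self.activity_weights_by_bin[bin_])
        for cat in _CATEGORIES:
            if cat not in self.duration_model:
                raise ConfigError(f"duration_model missing {cat}")
            mu, sigma = self.duration_model[cat]
            if sigma < 0:
                raise ConfigError(f"duration sd for {cat} must be >= 0")
        if self.frenzy_count < 0:
            raise ConfigError("frenzy_count must be >= 0")

    def normalized_weights(
        self, bin_: Optional[DielBin] = None
    ) -> dict[BehaviorCategory, float]:
        """Activity weights renormalized to sum exactly to one.

        Weights further than 0.5% from unit sum are rejected; the small slack
        absorbs budgets specified from rounded percentages.
        """
        raw = self.activity_weights
        if bin_ is not None and self.activity_weights_by_bin is not None:
            raw = self.activity_weights_by_bin[bin_]
        return _normalize_weights(raw)

    def resolved_site_split(self) -> tuple[int, int]:
        """Site split, defaulting to the study's 9:6 ratio of individuals."""
        if self.site_split is not None:
            return tuple(self.site_split)  # type: ignore[return-value]
        first = int(round(self.n_individuals * 9 / 15))
        return (first, self.n_individuals - first)

    # -- deployment layout ------------------------------------------------

    def deployments(self) -> list["Deployment"]:
        """Deterministic deployment layout implied by the configuration.

        Start clocks are staggered around the 24-h day so recording covers all
        diel bins; the 30-min schedule is spread evenly across deployments.
        """
        n = self.n_individuals
        n_half = int(round(self.half_hour_fraction * n))
        out: list[Deployment] = []
        for i in range(n):
            half = (i * n_half) % n < n_half if n_half > 0 else False
            exposure = 0.5 if half else 1.0
            if self.hours_per_deployment is not None:
                n_intervals = max(1, int(round(self.hours_per_deployment / exposure)))
            else:
                n_intervals = self.n_half_intervals if half else self.n_hour_intervals
            site = "MINWR_2010" if i < self.resolved_site_split()[0] else "Guana_2011"
            base = datetime(2010, 4, 23) if site == "MINWR_2010" else datetime(2011, 4, 28)
            start = base + timedelta(days=i, hours=(i * 24.0 / n) % 24.0)
            start = start.replace(microsecond=0)
            out.append(
                Deployment(
                    deployment_id=f"D{i + 1:02d}",
                    individual_id=f"A{i + 1:02d}",
                    site_year=site,
                    exposure_h=exposure,
                    n_intervals=n_intervals,
                    window_start=start,
                )
            )
        return out

    def potential_hours(self) -> float:
        return sum(d.exposure_h * d.n_intervals for d in self.deployments())


def _normalize_weights(raw: Mapping[BehaviorCategory, float]) -> dict[BehaviorCategory, float]:
    weights = {cat: float(raw.get(cat, 0.0)) for cat in _CATEGORIES}
    if any(w < 0 for w in weights.values()):
        raise ConfigError("activity weights must be >= 0")
    total = sum(weights.values())
    if abs(total - 1.0) > 5e-3:
        raise ConfigError(f"activity weights must sum to 1 (got {total:.4f})")
    return {cat: w / total for cat, w in weights.items()}


@dataclass(frozen=True)
class Deployment:
    """One camera deployment: an individual, a site/year and a recording plan."""

    deployment_id: str
    individual_id: str
    site_year: str
    exposure_h: float
    n_intervals: int
    window_start: datetime

    @property
    def window_seconds(self) -> int:
        return int(round(self.exposure_h * 3600)) * self.n_intervals


# ---------------------------------------------------------------------------
# activity bouts


def simulate_activity_bouts(cfg: SimConfig, seed: int) -> list[BehaviorBout]:
    """Simulate alternating-renewal activity bouts tiling each recording window.

    The next activity is drawn with probability proportional to its time
    weight divided by its mean bout duration (so the long-run *time* share of
    each activity converges to the configured weight), then a duration is
    drawn from that activity's lognormal.  When per-bin weights are set the
    weights of the bin containing the current clock time are used.  The final
    bout of each window is truncated so bouts exactly tile the window.
    """
    cfg.validate()
    rng = substream(seed, "bouts")
    mean_dur = {
        cat: float(np.exp(mu + sigma**2 / 2.0)) for cat, (mu, sigma) in cfg.duration_model.items()
    }

    def selection_probs(bin_: Optional[DielBin]) -> np.ndarray:
        w = cfg.normalized_weights(bin_)
        q = np.array([w[cat] / mean_dur[cat] for cat in _CATEGORIES])
        return q / q.sum()

    per_bin = cfg.activity_weights_by_bin is not None
    cached = None if per_bin else selection_probs(None)

    bouts: list[BehaviorBout] = []
    idx = np.arange(len(_CATEGORIES))
    for dep in cfg.deployments():
        elapsed = 0
        window = dep.window_seconds
        while elapsed < window:
            now = dep.window_start + timedelta(seconds=elapsed)
            bin_now = assign_diel_bin(now)
            probs = selection_probs(bin_now) if per_bin else cached
            cat = _CATEGORIES[int(rng.choice(idx, p=probs))]
            mu, sigma = cfg.duration_model[cat]
            if cfg.duration_shift_by_bin is not None:
                mu = mu + float(cfg.duration_shift_by_bin.get(bin_now, {}).get(cat, 0.0))
            dur = int(max(1, round(rng.lognormal(mean=mu, sigma=sigma))))
            dur = min(dur, window - elapsed)
            bouts.append(
                BehaviorBout(
                    deployment_id=dep.deployment_id,
                    individual_id=dep.individual_id,
                    activity=cat,
                    start=now,
                    duration_s=dur,
                )
            )
            elapsed += dur
    return bouts


# ---------------------------------------------------------------------------
# attack process


def cell_success_prob(cfg: SimConfig, bin_: DielBin, position: str) -> float:
    """Success probability for a (diel bin, water position) cell.

    With only one factor configured the cell probability equals the configured
    value exactly; with both, the effects combine additively on the logit
    scale relative to the anchor level, so neither factor's configured cell
    values are marginal probabilities but their ordering is preserved.
    """
    pb = cfg.success_probs_by_bin
    pp = cfg.success_probs_by_position
    if pb is None and pp is None:
        return cfg.success_anchor
    if pp is None:
        return float(pb[bin_])
    if pb is None:
        return float(pp[position])
    eta = logit(pb[bin_]) + logit(pp[position]) - logit(cfg.success_anchor)
    return float(expit(eta))


def simulate_attack_process(
    cfg: SimConfig, seed: int
) -> tuple[list[SamplingInterval], list[AttackRecord]]:
    """Simulate sampling intervals with Poisson attack counts and attack records.

    For interval *i* of individual *j* starting in diel bin *b*::

        count_i ~ Poisson(exposure_i * base_rate * multiplier_b * exp(u_j)),
        u_j ~ Normal(0, individual_sd**2)

    Attack timestamps are uniform within the interval; covariates are drawn
    from the configured marginals and outcomes are Bernoulli with the cell
    probability of the attack's own diel bin and water position.  Non-viable
    intervals contribute no observed attacks.
    """
    cfg.validate()
    rng_u = substream(seed, "intercepts")
    rng_iv = substream(seed, "intervals")
    rng_at = substream(seed, "attacks")

    deployments = cfg.deployments()
    u = {
        dep.individual_id: (rng_u.normal(0.0, cfg.individual_sd) if cfg.individual_sd > 0 else 0.0)
        for dep in deployments
    }

    intervals: list[SamplingInterval] = []
    attacks: list[AttackRecord] = []
    for dep in deployments:
        exposure_s = int(round(dep.exposure_h * 3600))
        for k in range(dep.n_intervals):
            start = dep.window_start + timedelta(seconds=k * exposure_s)
            viable = bool(rng_iv.random() < cfg.viable_fraction)
            count = 0
            if viable:
                mult = float(cfg.bin_rate_multipliers.get(assign_diel_bin(start), 1.0))
                lam = dep.exposure_h * cfg.base_attack_rate * mult * float(np.exp(u[dep.individual_id]))
                count = int(rng_iv.poisson(lam))
            intervals.append(
                SamplingInterval(
                    individual_id=dep.individual_id,
                    site_year=dep.site_year,
                    start=start,
                    exposure_h=dep.exposure_h,
                    attack_count=count,
                    viable=viable,
                )
            )
            attacks.extend(_draw_attacks(cfg, dep, start, exposure_s, count, rng_at))

    if cfg.feeding_frenzy:
        intervals, attacks = _inject_frenzy(cfg, intervals, attacks, rng_at)
    return intervals, attacks


def _draw_attacks(cfg, dep, start, exposure_s, count, rng) -> list[AttackRecord]:
    out = []
    offsets = np.sort(rng.integers(0, exposure_s, size=count)) if count else []
    for off in offsets:
        t = start + timedelta(seconds=int(off))
        position = "submerged" if rng.random() < cfg.p_submerged else "surface"
        mode = "sit_and_wait" if rng.random() < cfg.p_sit_and_wait else "active_search"
        habitat = "vegetation" if rng.random() < cfg.p_vegetation else "open_water"
        p = cell_success_prob(cfg, assign_diel_bin(t), position)
        outcome = "success" if rng.random() < p else "attempt_only"
        out.append(
            AttackRecord(
                individual_id=dep.individual_id,
                site_year=dep.site_year,
                time=t,
                water_position=position,
                hunting_mode=mode,
                habitat=habitat,
                outcome=outcome,
            )
        )
    return out


def _inject_frenzy(cfg, intervals, attacks, rng):
    """Replace one viable interval's count with a large outlier count."""
    target = next((i for i, iv in enumerate(intervals) if iv.viable), None)
    if target is None:
        return intervals, attacks
    iv = intervals[target]
    dep = Deployment(
        deployment_id="frenzy",
        individual_id=iv.individual_id,
        site_year=iv.site_year,
        exposure_h=iv.exposure_h,
        n_intervals=1,
        window_start=iv.start,
    )
    exposure_s = int(round(iv.exposure_h * 3600))
    attacks = [
        a
        for a in attacks
        if not (a.individual_id == iv.individual_id and iv.start <= a.time < iv.start + timedelta(seconds=exposure_s))
    ]
    intervals[target] = dataclasses.replace(iv, attack_count=cfg.frenzy_count)
    attacks.extend(_draw_attacks(cfg, dep, iv.start, exposure_s, cfg.frenzy_count, rng))
    attacks.sort(key=lambda a: (a.individual_id, a.time))
    return intervals, attacks


# ---------------------------------------------------------------------------
# study writer


def generate_study(cfg: SimConfig, out_dir, seed: int) -> dict[str, Path]:
    """Simulate a full study and write its three CSV tables plus a manifest.

    The manifest records the exact configuration, seed and package version so
    every output directory is self-describing.  Files round-trip through the
    :mod:`ethoforage.io` readers.
    """
    import yaml

    from ethoforage import __version__
    from ethoforage.io import write_attack_table, write_bout_table, write_interval_table

    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bouts = simulate_activity_bouts(cfg, seed)
    intervals, attacks = simulate_attack_process(cfg, seed)

    paths = {
        "bouts": out_dir / "bouts.csv",
        "intervals": out_dir / "intervals.csv",
        "attacks": out_dir / "attacks.csv",
        "manifest": out_dir / "manifest.yaml",
    }
    write_bout_table(bouts, paths["bouts"])
    write_interval_table(intervals, paths["intervals"])
    write_attack_table(attacks, paths["attacks"])

    manifest = {
        "generator": "ethoforage.simulate.generate_study",
        "version": __version__,
        "seed": int(seed),
        "config": _config_to_plain(cfg),
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def _config_to_plain(cfg: SimConfig) -> dict:
    def plain(obj):
        if isinstance(obj, Mapping):
            return {plain(k): plain(v) for k, v in obj.items()}
        if isinstance(obj, (BehaviorCategory, DielBin)):
            return obj.value
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return plain(dataclasses.asdict(cfg))
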