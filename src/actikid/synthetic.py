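"""Synthetic wearable-cohort generator with known ground truth.

Emulates the structure of a young-children (12-36 months) accelerometry
cohort so the whole pipeline can be exercised and validated without any
real data: per-child epoch count traces generated from a six-state
explicit-duration semi-Markov model with Gaussian magnitudes and shifted-
Poisson dwells; a diurnal wear schedule (device on roughly 07:09-10:09 to
18:18-20:33, with a probabilistic midday nap removal of 70-110 min); and a
covariate table (age, sex, deprivation decile, recruitment pathway,
mobility and social-cognitive capacity scores correlated at rho = 0.8,
19 ordinal parent-action items, carer work hours, time to outdoors, daily
maximum temperature, and 23 HRQoL items on a 0-4 scale).

Ground truth is planted on a latent activity propensity: each child's
target occupancy of the intense states (4-5) — and of the active states
(2-3) for the total-active outcome — is a linear function of standardized
covariates plus Gaussian noise, realized by scaling the dwell rates of the
corresponding states. The generator records the propensities and targets in
a manifest so downstream recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsmm import NON_WEAR_LABEL, HSMMParams
from .prep import MINIMAL_MOVEMENT_COUNTS_PER_SEC, EpochSeries, write_epoch_series


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# True model defaults (per-second scale, converted to the epoch length)
# ---------------------------------------------------------------------------

#: Gaussian emission means / SDs in counts per second of epoch for the six
#: states, ascending in intensity; dwell means in seconds beyond the 1-epoch
#: minimum. Chosen to give a cohort baseline of roughly 62% of wear time in
#: states 2-5 and 29% in states 4-5.
_MU_PER_SEC = np.array([1.0, 5.0, 12.0, 22.0, 35.0, 55.0])
_SD_PER_SEC = np.array([1.5, 3.0, 5.0, 8.0, 11.0, 15.0])
_DWELL_SECONDS = np.array([25.0, 14.0, 20.0, 16.0, 18.0, 14.0])

INACTIVE_STATES = (0, 1)
MID_STATES = (2, 3)
INTENSE_STATES = (4, 5)


def default_true_model(epoch_seconds: float = 1.0) -> HSMMParams:
    """Ground-truth six-state model scaled to the epoch length.

    Counts accumulate over the epoch, so means scale linearly and SDs with
    the square root of the epoch length; dwell rates are expressed in epochs.
    """
    k = 6
    trans = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(trans, 0.0)
    return HSMMParams(
        initial=np.full(k, 1.0 / k),
        transition=trans,
        means=_MU_PER_SEC * epoch_seconds,
        sds=_SD_PER_SEC * np.sqrt(epoch_seconds),
        rates=np.maximum(_DWELL_SECONDS / epoch_seconds, 0.2),
        max_duration=max(int(round(600.0 / epoch_seconds)), 30),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class WearSchedule:
    """Per-day wear window and nap-removal distributions (hours of day)."""

    start_window: tuple = (7.15, 10.15)  # 07:09-10:09
    end_window: tuple = (18.30, 20.55)  # 18:18-20:33
    nap_probability: float = 0.8
    nap_window: tuple = (12.0, 14.0)
    nap_minutes: tuple = (70.0, 110.0)
    day_start_hour: float = 6.0  # trace coverage (device off outside wear)
    day_end_hour: float = 21.5


DEFAULT_MISSINGNESS = {
    "mobility": 0.106,
    "social_cognitive": 0.106,
    "carer_work_hours": 0.05,
    "time_to_outdoors": 0.08,
    **{f"parent_action_{i}": 0.02 for i in range(1, 20)},
}


@dataclass
class SyntheticConfig:
    n_children: int = 282
    n_days: int = 7
    epoch_seconds: float = 1.0
    true_hsmm: HSMMParams | None = None
    wear: WearSchedule = field(default_factory=WearSchedule)
    mobility_rho: float = 0.8
    # planted standardized effects on the latent activity propensities
    effects_active: dict = field(
        default_factory=lambda: {"mobility": 0.41, "parent_action_9": -0.17}
    )
    effects_intense: dict = field(default_factory=lambda: {"mobility": 0.76})
    noise_sd_active: float | None = None  # None: set so Var(propensity) = 1
    noise_sd_intense: float | None = None
    # occupancy link: target proportion = base + sd * propensity
    base_prop_active: float = 0.62
    sd_prop_active: float = 0.11
    base_prop_intense: float = 0.29
    sd_prop_intense: float = 0.05
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    pedsql_block_missing: float = 0.60
    seed: int = 0
    first_date: str = "2019-06-03"

    def __post_init__(self):
        if self.n_children < 1 or self.n_days < 1:
            raise ConfigError("n_children and n_days must be >= 1")
        if self.epoch_seconds <= 0:
            raise ConfigError("epoch_seconds must be positive")
        for eff in (self.effects_active, self.effects_intense):
            if eff and not all(np.isfinite(list(eff.values()))):
                raise ConfigError("effect sizes must be finite")
        if not -1 < self.mobility_rho < 1:
            raise ConfigError("mobility_rho must be in (-1, 1)")
        if any(not 0 <= p <= 1 for p in self.missingness.values()):
            raise ConfigError("missingness probabilities must be in [0, 1]")
        if self.true_hsmm is None:
            self.true_hsmm = default_true_model(self.epoch_seconds)
        if np.any(self.true_hsmm.rates <= 0) or np.any(self.true_hsmm.sds <= 0):
            raise ConfigError("true model dwell rates and SDs must be positive")


@dataclass
class ChildProfile:
    child_id: str
    age_months: int
    sex: int  # 0 female, 1 male
    imd_decile: int
    pathway: int  # 0 universal, 1 specialist
    mobility: float
    social_cognitive: float
    parent_actions: np.ndarray  # 19 ordinal items, 0-4
    carer_work_hours: float
    time_to_outdoors: float
    max_daily_temp: np.ndarray  # one value per recording day
    pedsql_items: np.ndarray  # 23 items, 0-4
    # filled by generate_cohort from the planted propensities
    target_prop_active: float | None = None
    target_prop_intense: float | None = None


# observed cohort-like marginals
_IMD_PROBS = np.array([13.4, 10.5, 7.9, 6.9, 7.9, 9.0, 13.0, 5.8, 13.0, 12.6])
_IMD_PROBS = _IMD_PROBS / _IMD_PROBS.sum()
_P_FEMALE = 0.564
_P_SPECIALIST = 118 / 282


def generate_profiles(config: SyntheticConfig, rng=None) -> list[ChildProfile]:
    """Draw per-child covariate profiles from the configured marginals."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_children
    ages = _truncated_normal(rng, 21.0, 8.0, 12.0, 36.0, n).round().astype(int)
    sexes = (rng.random(n) >= _P_FEMALE).astype(int)
    imd = rng.choice(np.arange(1, 11), size=n, p=_IMD_PROBS)
    pathway = (rng.random(n) < _P_SPECIALIST).astype(int)
    # mobility and social-cognitive capacity from a latent bivariate normal
    rho = config.mobility_rho
    z_mob = rng.standard_normal(n)
    z_soc = rho * z_mob + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    # specialist-pathway children tend to score lower on both
    shift = 0.5 * pathway
    mobility = 56.8 + 6.6 * (z_mob - shift)
    social = 55.2 + 4.8 * (z_soc - shift)
    pa_latent = rng.standard_normal((n, 19))
    pa = _ordinal_from_latent(pa_latent)
    carer = np.clip(rng.gamma(1.3, 17.0, n), 0, 80).round(1)
    outdoors = np.clip(rng.gamma(2.0, 6.0, n), 1, 90).round(0)
    temps = rng.normal(14.0, 5.0, (n, config.n_days)).round(1)
    hrq_latent = np.exp(rng.normal(np.log(0.8), 0.6, n)).clip(0.0, 4.0)
    items = np.clip(
        np.round(hrq_latent[:, None] + rng.normal(0.0, 0.8, (n, 23))), 0, 4
    ).astype(int)
    width = len(str(n))
    return [
        ChildProfile(
            child_id=f"child{str(i + 1).zfill(width)}",
            age_months=int(ages[i]),
            sex=int(sexes[i]),
            imd_decile=int(imd[i]),
            pathway=int(pathway[i]),
            mobility=float(round(mobility[i], 1)),
            social_cognitive=float(round(social[i], 1)),
            parent_actions=pa[i],
            carer_work_hours=float(carer[i]),
            time_to_outdoors=float(outdoors[i]),
            max_daily_temp=temps[i],
            pedsql_items=items[i],
        )
        for i in range(n)
    ]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def _ordinal_from_latent(z: np.ndarray) -> np.ndarray:
    """5-level ordinal frequency items from latent normals (0 = never ...
    4 = very often)."""
    cuts = np.array([-1.5, -0.5, 0.5, 1.5])
    return np.searchsorted(cuts, z).astype(int)


def profiles_frame(profiles: list[ChildProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "child_id": p.child_id,
            "age_months": p.age_months,
            "sex": p.sex,
            "imd_decile": p.imd_decile,
            "pathway": p.pathway,
            "mobility": p.mobility,
            "social_cognitive": p.social_cognitive,
            "carer_work_hours": p.carer_work_hours,
            "time_to_outdoors": p.time_to_outdoors,
            "max_daily_temp": float(np.mean(p.max_daily_temp)),
        }
        row.update({f"parent_action_{i + 1}": int(v) for i, v in enumerate(p.parent_actions)})
        row.update({f"pedsql_item_{i + 1}": int(v) for i, v in enumerate(p.pedsql_items)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------


def _embedded_stationary(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of the embedded (jump) chain."""
    k = transition.shape[0]
    if k == 1:
        return np.ones(1)
    w, v = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    nu = np.real(v[:, i])
    nu = np.abs(nu)
    return nu / nu.sum()


def semi_markov_occupancy(params: HSMMParams) -> np.ndarray:
    """Long-run fraction of epochs in each state: nu_k (1 + lambda_k),
    normalized, with nu the embedded-chain stationary distribution."""
    nu = _embedded_stationary(params.transition)
    occ = nu * (1.0 + params.rates)
    return occ / occ.sum()


def dwell_multipliers(
    params: HSMMParams, target_active: float, target_intense: float
) -> tuple[float, float]:
    """Dwell-rate multipliers for states 2-3 and 4-5 that set the long-run
    occupancy of states 2-5 to ``target_active`` and of 4-5 to
    ``target_intense``. Closed form via the occupancy identity above."""
    nu = _embedded_stationary(params.transition)
    lam = params.rates
    f_int = float(np.clip(target_intense, 0.05, 0.55))
    f_act = float(np.clip(target_active, f_int + 0.08, 0.92))
    f01, f23, f45 = 1.0 - f_act, f_act - f_int, f_int
    w01 = sum(nu[k] * (1.0 + lam[k]) for k in INACTIVE_STATES)
    m = {}
    for states, f in ((MID_STATES, f23), (INTENSE_STATES, f45)):
        c = sum(nu[k] for k in states)
        v = sum(nu[k] * lam[k] for k in states)
        m[states] = max((w01 * f / f01 - c) / v, 0.02)
    return m[MID_STATES], m[INTENSE_STATES]


def _child_model(params: HSMMParams, profile: ChildProfile) -> HSMMParams:
    if profile.target_prop_active is None or profile.target_prop_intense is None:
        return params
    m23, m45 = dwell_multipliers(
        params, profile.target_prop_active, profile.target_prop_intense
    )
    rates = params.rates.copy()
    rates[list(MID_STATES)] *= m23
    rates[list(INTENSE_STATES)] *= m45
    return HSMMParams(
        initial=params.initial,
        transition=params.transition,
        means=params.means,
        sds=params.sds,
        rates=rates,
        max_duration=params.max_duration,
    )


def _simulate_chain(params: HSMMParams, n_epochs: int, rng) -> np.ndarray:
    """State label per epoch for one wear block: explicit-duration
    semi-Markov chain, dwell = 1 + Poisson(rate)."""
    k = params.n_states
    if k == 1:
        return np.zeros(n_epochs, dtype=np.int64)
    cum = np.cumsum(params.transition, axis=1)
    mean_dwell = float(np.mean(1.0 + params.rates))
    states = []
    total = 0
    state = int(np.searchsorted(np.cumsum(params.initial), rng.random()))
    while total < n_epochs:
        batch = max(int((n_epochs - total) / mean_dwell * 1.3) + 8, 16)
        seq = np.empty(batch, dtype=np.int64)
        u = rng.random(batch)
        for i in range(batch):
            seq[i] = state
            state = int(np.searchsorted(cum[state], u[i]))
        dwells = 1 + rng.poisson(params.rates[seq])
        states.append(np.repeat(seq, dwells))
        total += int(dwells.sum())
    return np.concatenate(states)[:n_epochs]


def _truncated_gaussian_counts(means, sds, rng) -> np.ndarray:
    """Per-epoch magnitudes ~ N(mu, sd^2) truncated at zero (counts are
    non-negative), by vectorized rejection."""
    out = rng.normal(means, sds)
    for _ in range(200):
        bad = out < 0
        if not bad.any():
            break
        out[bad] = rng.normal(means[bad], sds[bad])
    return np.maximum(out, 0.0)


def simulate_trace(
    profile: ChildProfile, config: SyntheticConfig, rng=None
) -> tuple[EpochSeries, np.ndarray]:
    """Simulate one child's full trace plus true per-epoch state labels.

    Within scheduled wear the states evolve as the explicit-duration chain
    (restarted across non-wear gaps); scheduled non-wear epochs carry
    sub-threshold magnitudes and label -1. Labels are returned for
    evaluation only.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    params = _child_model(config.true_hsmm, profile)
    eps = config.epoch_seconds
    ws = config.wear
    day_epochs = (ws.day_end_hour - ws.day_start_hour) * 3600.0 / eps
    if abs(day_epochs - round(day_epochs)) > 1e-9:
        raise ConfigError("epoch length must divide the daily trace span")
    day_epochs = int(round(day_epochs))
    threshold = MINIMAL_MOVEMENT_COUNTS_PER_SEC * eps
    all_mags, all_labels = [], []
    for _ in range(config.n_days):
        start_h = rng.uniform(*ws.start_window)
        end_h = rng.uniform(*ws.end_window)
        wear = np.zeros(day_epochs, dtype=bool)
        i0 = int(round((start_h - ws.day_start_hour) * 3600 / eps))
        i1 = int(round((end_h - ws.day_start_hour) * 3600 / eps))
        wear[i0:i1] = True
        if rng.random() < ws.nap_probability:
            nap_len_h = rng.uniform(*ws.nap_minutes) / 60.0
            nap_lo, nap_hi = ws.nap_window
            nap_start = rng.uniform(nap_lo, max(nap_hi - nap_len_h, nap_lo))
            j0 = int(round((nap_start - ws.day_start_hour) * 3600 / eps))
            j1 = int(round((nap_start + nap_len_h - ws.day_start_hour) * 3600 / eps))
            wear[j0:j1] = False
        labels = np.full(day_epochs, NON_WEAR_LABEL, dtype=np.int64)
        mags = rng.uniform(0.0, 0.8 * threshold, day_epochs)
        edges = np.concatenate(
            [[0], np.flatnonzero(np.diff(wear.astype(np.int8)) != 0) + 1, [day_epochs]]
        )
        for a, b in zip(edges[:-1], edges[1:]):
            if wear[a] and b > a:
                st = _simulate_chain(params, b - a, rng)
                labels[a:b] = st
                mags[a:b] = _truncated_gaussian_counts(
                    params.means[st], params.sds[st], rng
                )
        all_mags.append(mags)
        all_labels.append(labels)
    start = np.datetime64(config.first_date) + np.timedelta64(
        int(ws.day_start_hour * 3600), "s"
    )
    # trace days are concatenated on the clock grid; the gap between
    # day_end_hour and next day_start_hour is absent from the file and is
    # zero-filled on read (also non-wear)
    n_gap = int(round((24.0 - (ws.day_end_hour - ws.day_start_hour)) * 3600 / eps))
    mags = _join_days(all_mags, n_gap)
    labels = _join_days(all_labels, n_gap, fill=NON_WEAR_LABEL)
    series = EpochSeries(
        child_id=profile.child_id, start_time=start, epoch_seconds=eps, magnitudes=mags
    )
    return series, labels


def _join_days(chunks, n_gap, fill=0.0):
    joined = []
    for i, c in enumerate(chunks):
        joined.append(c)
        if i < len(chunks) - 1:
            joined.append(np.full(n_gap, fill, dtype=c.dtype))
    return np.concatenate(joined)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    profiles: list
    traces: list  # EpochSeries per child
    true_labels: list  # int arrays aligned with traces
    table: pd.DataFrame  # covariates (+ HRQoL items) with MCAR missingness
    manifest: dict  # ground truth: planted effects, propensities, targets


def _standardize_columns(df: pd.DataFrame, cols) -> pd.DataFrame:
    z = df[list(cols)].astype(float)
    sd = z.std(ddof=1)
    # a column with no variation (tiny cohorts) carries no plantable signal
    sd = sd.where(np.isfinite(sd) & (sd > 0), np.inf)
    return (z - z.mean()) / sd


def generate_cohort(
    config: SyntheticConfig, out_dir=None, simulate_traces: bool = True
) -> SyntheticCohort:
    """Generate profiles, planted activity propensities, traces and the
    covariate table; optionally write everything under ``out_dir``.

    The intense-activity propensity of child i is
    ``sum_j beta_j z_ij + N(0, noise_sd)`` over the empirically standardized
    covariates named in ``effects_intense`` (likewise for the total-active
    propensity), realized in the trace by scaling the dwell rates of states
    4-5 (2-3) so the long-run occupancy hits
    ``base + sd * propensity``.
    """
    rng = np.random.default_rng(config.seed)
    profiles = generate_profiles(config, rng)
    full = profiles_frame(profiles)  # pre-missingness covariates
    eta = {}
    for name, effects, noise_sd in (
        ("active", config.effects_active, config.noise_sd_active),
        ("intense", config.effects_intense, config.noise_sd_intense),
    ):
        beta = np.array(list(effects.values()), dtype=float)
        if noise_sd is None:
            noise_sd = float(np.sqrt(max(1.0 - beta @ beta, 0.04)))
        lin = np.zeros(config.n_children)
        if effects:
            z = _standardize_columns(full, effects.keys()).to_numpy()
            lin = z @ beta
        eta[name] = lin + rng.normal(0.0, noise_sd, config.n_children)
        eta[f"{name}_noise_sd"] = noise_sd
    targets_a = config.base_prop_active + config.sd_prop_active * eta["active"]
    targets_i = config.base_prop_intense + config.sd_prop_intense * eta["intense"]
    for i, p in enumerate(profiles):
        p.target_prop_active = float(targets_a[i])
        p.target_prop_intense = float(targets_i[i])

    traces, labels = [], []
    if simulate_traces:
        for p in profiles:
            series, lab = simulate_trace(p, config, rng)
            traces.append(series)
            labels.append(lab)

    table = full.drop(columns=[c for c in full.columns if c.startswith("pedsql_")])
    item_cols = [c for c in full.columns if c.startswith("pedsql_item_")]
    items = full[item_cols].astype(float)
    # MCAR missingness: per-column rates plus questionnaire-level removal of
    # the whole HRQoL block
    for col, p_miss in config.missingness.items():
        if col in table.columns and p_miss > 0:
            table.loc[rng.random(len(table)) < p_miss, col] = np.nan
    block = rng.random(len(table)) < config.pedsql_block_missing
    items.loc[block, :] = np.nan
    table = pd.concat([table, items], axis=1)

    manifest = {
        "schema": "actikid-cohort/1",
        "seed": config.seed,
        "n_children": config.n_children,
        "n_days": config.n_days,
        "epoch_seconds": config.epoch_seconds,
        "effects_active": dict(config.effects_active),
        "effects_intense": dict(config.effects_intense),
        "noise_sd_active": eta["active_noise_sd"],
        "noise_sd_intense": eta["intense_noise_sd"],
        "base_prop_active": config.base_prop_active,
        "sd_prop_active": config.sd_prop_active,
        "base_prop_intense": config.base_prop_intense,
        "sd_prop_intense": config.sd_prop_intense,
        "true_model": config.true_hsmm.to_dict(),
        "children": [
            {
                "child_id": p.child_id,
                "eta_active": float(eta["active"][i]),
                "eta_intense": float(eta["intense"][i]),
                "target_prop_active": p.target_prop_active,
                "target_prop_intense": p.target_prop_intense,
            }
            for i, p in enumerate(profiles)
        ],
    }
    cohort = SyntheticCohort(
        config=config,
        profiles=profiles,
        traces=traces,
        true_labels=labels,
        table=table,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_cohort(cohort, out_dir)
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    import os

    traces_dir = os.path.join(str(out_dir), "traces")
    try:
        os.makedirs(traces_dir, exist_ok=True)
        for series in cohort.traces:
            write_epoch_series(series, os.path.join(traces_dir, f"{series.child_id}.csv"))
        cohort.table.to_csv(os.path.join(str(out_dir), "cohort.csv"), index=False)
        with open(os.path.join(str(out_dir), "manifest.json"), "w") as fh:
            json.dump(cohort.manifest, fh, indent=1)
    except OSError as exc:
        raise OSError(f"cannot write cohort under {out_dir}: {exc}") from exc
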