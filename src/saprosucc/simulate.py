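"""Synthetic colonization-extinction studies with known ground truth.

The generator emulates a balanced trap design (by default 15 traps per
environment per landscape, 4 study years) over a species pool split
into host-affinity and guild cells.  Each species colonizes a trap at
most once: the year of first arrival is drawn from an
environment-specific hazard profile (front-loaded at sun-exposed sites,
flat at shaded sites), after which the species persists year-to-year
with a geometric survival probability.  Sampling is imperfect: a
present species is detected each year with a fixed Bernoulli
probability and, when detected, yields a zero-truncated negative
binomial (NB2) count.

Real assemblages are not exchangeable within functional groups, so each
species also carries three latent traits drawn once from the parameter
seed: an environment preference (log-scale tilt of its colonization
probability toward sun or shade), a timing tilt (early- vs
late-colonizing), and an abundance multiplier (lognormal, mean 1).
These give the community the species-level structure that ordination
and variance partitioning operate on.  A latent per-trap fungal
resource (lognormal, environment-dependent mean) scales the
colonization probability of fungivores and drives the observed
fungal-diversity covariate (a small Poisson count saturating in the
resource), mimicking fruit-body surveys covarying with fungivorous
beetles.

All randomness flows from one seed through named child streams
(arrival, survival, detection, counts, fungal); the species-trait
stream is tied to ``params.seed`` so that replicate studies (different
run seeds) share one species pool.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .datamodel import (
    CommunityMatrix,
    SiteTable,
    TraitTable,
    community_from_long,
)

ENVS = ("exposed", "shaded")


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of a synthetic study.

    ``arrival`` maps affinity -> environment -> length-T tuple: the
    probability that a species first becomes present in each year
    (year 1 entries are initial colonization); entries sum to <= 1,
    the remainder never arriving.  ``persistence`` is the annual
    probability of remaining present.  ``mu``/``theta`` parameterize
    the NB2 count for a detected species (variance mu + mu^2/theta),
    with ``exposed_multiplier`` scaling mu at sun-exposed sites.
    """

    n_traps_per_env_per_landscape: int = 15
    n_years: int = 4
    pool: dict = field(default_factory=lambda: {
        # affinity -> guild -> n species; proportions follow typical
        # saproxylic assemblages on aspen (17 specialists, 167 generalists)
        "specialist": {"wood_feeder": 5, "fungivore": 8,
                       "predator": 2, "omnivore_saprophage": 2},
        "generalist": {"wood_feeder": 17, "fungivore": 65,
                       "predator": 73, "omnivore_saprophage": 12},
    })
    arrival: dict = field(default_factory=lambda: {
        "specialist": {
            "exposed": (0.06, 0.45, 0.08, 0.04),
            "shaded": (0.05, 0.08, 0.08, 0.08),
        },
        "generalist": {
            "exposed": (0.11, 0.16, 0.05, 0.03),
            "shaded": (0.08, 0.09, 0.09, 0.09),
        },
    })
    persistence: dict = field(default_factory=lambda: {
        "exposed": 0.65, "shaded": 0.75,
    })
    detection: float = 0.55
    mu: float = 1.2
    theta: float = 1.0
    exposed_multiplier: float = 1.8
    # per-affinity sd of the latent species traits (scalar = same for all)
    env_pref_sd: object = field(default_factory=lambda: {
        "specialist": 1.0, "generalist": 1.9,
    })
    timing_sd: object = field(default_factory=lambda: {
        "specialist": 0.35, "generalist": 1.3,
    })
    abundance_sd: float = 0.8   # sd of per-species log abundance multiplier
    abundance_trend_sd: float = 0.5  # sd of per-species log count trend/year
    # latent per-trap fungal resource: scales fungivore colonization and
    # drives the fungal-diversity covariate
    fungal_resource_mean: dict = field(default_factory=lambda: {
        "exposed": 0.4, "shaded": -0.2,
    })
    fungal_resource_sd: float = 1.0
    fungal_presence_coef: float = 2.0  # fungivore arrival ~ resource^coef
    fungal_lambda: dict = field(default_factory=lambda: {
        "exposed": 0.3, "shaded": 0.3,
    })
    fungal_resource_coef: float = 3.0  # fd mean per unit log1p(resource)
    landscapes: tuple = ("A", "B")
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.detection <= 1:
            raise ValueError("detection must be a probability")
        if self.theta <= 0 or self.mu <= 0:
            raise ValueError("mu and theta must be positive")
        for aff, by_env in self.arrival.items():
            for env, prof in by_env.items():
                prof = tuple(prof)
                if len(prof) != self.n_years:
                    raise ValueError(
                        f"arrival profile {aff}/{env} must have length "
                        f"{self.n_years}"
                    )
                if any(p < 0 or p > 1 for p in prof) or sum(prof) > 1 + 1e-12:
                    raise ValueError(
                        f"arrival profile {aff}/{env} must be probabilities "
                        "summing to <= 1"
                    )
        for env, s in self.persistence.items():
            if not 0 <= s <= 1:
                raise ValueError(f"persistence[{env}] must be a probability")

    @classmethod
    def aspen_study(cls, **overrides) -> "SimulationParams":
        """The default preset: the 60-stump aspen field design (see class defaults)."""
        return cls(**overrides)

    def species_table(self) -> pd.DataFrame:
        rows = []
        i = 0
        for aff in sorted(self.pool):
            for guild in sorted(self.pool[aff]):
                for _ in range(self.pool[aff][guild]):
                    i += 1
                    rows.append(dict(species=f"sp{i:03d}",
                                     host_affinity=aff, guild=guild))
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulatedStudy:
    community: CommunityMatrix
    traits: TraitTable
    sites: SiteTable
    ground_truth: dict

    def write_csvs(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.community.to_csv(outdir / "community.csv")
        self.traits.to_csv(outdir / "traits.csv")
        self.sites.to_csv(outdir / "sites.csv")
        gt = {k: v for k, v in self.ground_truth.items()
              if k not in ("latent_presence", "observed_presence")}
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(gt, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


_SPECIES_STREAM_SALT = 987654321


def species_effects(params: SimulationParams) -> pd.DataFrame:
    """Latent per-species traits, fixed by ``params.seed``.

    env_pref > 0 tilts colonization toward sun-exposed sites; timing > 0
    delays it (late colonizer); abund_mult scales the species' expected
    count (lognormal with mean 1).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, _SPECIES_STREAM_SALT])
    )
    species = params.species_table()
    n = len(species)

    def per_affinity(value):
        if isinstance(value, dict):
            return species["host_affinity"].map(value).to_numpy(float)
        return np.full(n, float(value))

    species["env_pref"] = rng.normal(0.0, per_affinity(params.env_pref_sd), n)
    species["timing"] = rng.normal(0.0, per_affinity(params.timing_sd), n)
    species["abund_mult"] = np.exp(
        rng.normal(-params.abundance_sd ** 2 / 2, params.abundance_sd, n)
    )
    species["abund_trend"] = rng.normal(0.0, params.abundance_trend_sd, n)
    return species


def species_profiles(params: SimulationParams,
                     effects: pd.DataFrame) -> np.ndarray:
    """Per-species arrival profiles, shape (n_species, n_envs, T).

    The affinity x environment base profile is tilted in time by the
    species' timing trait (mass redistributed, total preserved), then
    scaled up/down by its environment preference; profile sums are
    capped at 1 (certain arrival).
    """
    T = params.n_years
    out = np.zeros((len(effects), len(ENVS), T))
    years = np.arange(T)
    for i, row in enumerate(effects.itertuples(index=False)):
        for j, env in enumerate(ENVS):
            base = np.asarray(params.arrival[row.host_affinity][env], float)
            total = base.sum()
            prof = base * np.exp(row.timing * years)
            if prof.sum() > 0:
                prof *= total / prof.sum()
            prof = prof * np.exp(row.env_pref / 2 if env == "exposed"
                                 else -row.env_pref / 2)
            s = prof.sum()
            if s > 1.0:
                prof *= 1.0 / s
            out[i, j] = prof
    return out


def _streams(seed: int, names):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}


def _sample_ztnb(rng, mu, theta, size):
    """Zero-truncated NB2 via inverse-cdf above the zero mass."""
    p = theta / (theta + mu)
    p0 = p ** theta
    u = rng.uniform(low=p0, high=1.0, size=size)
    return nbinom.ppf(u, theta, p).astype(np.int64)


def simulate_study(params: SimulationParams, seed: int | None = None) -> SimulatedStudy:
    """Draw one synthetic study; reproducible given (params, seed)."""
    seed = params.seed if seed is None else seed
    rngs = _streams(
        seed,
        ["arrival", "survival", "detection", "counts", "fungal", "resource"],
    )
    T = params.n_years
    species = species_effects(params)
    profiles = species_profiles(params, species)
    ns = len(species)

    traps = []
    for lsc in params.landscapes:
        for env in ENVS:
            for i in range(params.n_traps_per_env_per_landscape):
                traps.append(dict(trap=f"{lsc}_{env[:3]}_{i+1:02d}",
                                  environment=env, landscape=lsc))
    sites_df = pd.DataFrame(traps)
    nt = len(sites_df)

    # latent per-trap fungal resource: lognormal, env-dependent mean; it
    # scales fungivore colonization and counts and drives the observed
    # fungal-diversity covariate
    resource = np.exp(rngs["resource"].normal(
        sites_df["environment"].map(params.fungal_resource_mean).to_numpy(),
        params.fungal_resource_sd,
    ))
    fung_mask = (species["guild"] == "fungivore").to_numpy()

    # arrival year per (trap, species): 1..T or 0 (never)
    env_idx = (sites_df["environment"] == "shaded").to_numpy().astype(int)
    prof = profiles[:, env_idx, :].transpose(1, 0, 2).copy()  # (nt, ns, T)
    prof[:, fung_mask, :] *= (
        resource ** params.fungal_presence_coef
    )[:, None, None]
    tot = prof.sum(axis=2, keepdims=True)
    np.divide(prof, tot, out=prof, where=tot > 1.0)
    cum = prof.cumsum(axis=2)
    u = rngs["arrival"].random((nt, ns, 1))
    arrival = (u < cum).argmax(axis=2) + 1
    arrival[u[:, :, 0] >= cum[:, :, -1]] = 0  # never arrives

    surv_p = sites_df["environment"].map(params.persistence).to_numpy()
    surv = rngs["survival"].random((nt, ns, T)) < surv_p[:, None, None]
    latent = np.zeros((nt, ns, T), dtype=bool)
    latent[:, :, 0] = arrival == 1
    for t in range(1, T):
        latent[:, :, t] = (arrival == t + 1) | (latent[:, :, t - 1] & surv[:, :, t])

    detected = rngs["detection"].random((nt, ns, T)) < params.detection
    observed = latent & detected

    mu_trap = np.where(
        sites_df["environment"].to_numpy() == "exposed",
        params.mu * params.exposed_multiplier,
        params.mu,
    )
    abund = species["abund_mult"].to_numpy()
    trend = species["abund_trend"].to_numpy()
    ti, si, yi = np.nonzero(observed)
    counts = np.zeros(len(ti), dtype=np.int64)
    if len(ti):
        # per-species count trend over years, centered so the expected
        # multiplier is 1 in every year
        dy = (yi + 1) - (T + 1) / 2
        trend_mult = np.exp(
            trend[si] * dy - (params.abundance_trend_sd * dy) ** 2 / 2
        )
        mu_obs = mu_trap[ti] * abund[si] * trend_mult
        counts = _sample_ztnb(rngs["counts"], mu_obs, params.theta, len(ti))

    long = pd.DataFrame({
        "trap": sites_df["trap"].to_numpy()[ti],
        "year": yi + 1,
        "species": species["species"].to_numpy()[si],
        "count": counts,
    }).sort_values(["trap", "year", "species"]).reset_index(drop=True)

    community = community_from_long(
        long,
        traps=tuple(sites_df["trap"]),
        years=tuple(range(1, T + 1)),
        species=tuple(species["species"]),
        recode_years=False,
    )
    # fruit-body diversity is a small count saturating in the resource
    fd_mean = (
        sites_df["environment"].map(params.fungal_lambda).to_numpy()
        + params.fungal_resource_coef * np.log1p(resource)
    )
    fungal = rngs["fungal"].poisson(fd_mean)
    sites = SiteTable(sites_df.assign(fungal_diversity=fungal))
    traits = TraitTable(species[["species", "host_affinity", "guild"]])
    ground_truth = {
        "seed": int(seed),
        "params": asdict(params),
        "latent_presence": latent,
        "observed_presence": observed,
        "arrival_year": arrival,
        "trap_order": list(sites_df["trap"]),
        "species_order": list(species["species"]),
        "species_effects": {
            "env_pref": species["env_pref"].to_numpy(),
            "timing": species["timing"].to_numpy(),
            "abund_mult": species["abund_mult"].to_numpy(),
        },
    }
    return SimulatedStudy(community=community, traits=traits,
                          sites=sites, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# analytic / Monte-Carlo expectations

def observed_pattern_distribution(profile, persistence, detection, T) -> np.ndarray:
    """Exact distribution over the 2^T observed presence patterns for one
    species (bit t of the pattern index = observed in year t+1)."""
    probs = np.zeros(2 ** T)
    profile = tuple(profile)
    probs[0] = 1.0 - sum(profile)
    for a in range(1, T + 1):
        pa = profile[a - 1]
        if pa == 0:
            continue
        for b in range(a, T + 1):
            if b < T:
                pb = persistence ** (b - a) * (1 - persistence)
            else:
                pb = persistence ** (T - a)
            run = list(range(a - 1, b))  # 0-based latent years
            for mask in itertools.product([0, 1], repeat=len(run)):
                pdet = 1.0
                code = 0
                for yr, bit in zip(run, mask):
                    pdet *= detection if bit else (1 - detection)
                    code |= bit << yr
                probs[code] += pa * pb * pdet
    assert abs(probs.sum() - 1.0) < 1e-12
    return probs


def _pattern_stats(T):
    """Per-pattern gain/loss indicators and per-year presence."""
    npat = 2 ** T
    present = np.zeros((npat, T), dtype=np.int64)
    for code in range(npat):
        for t in range(T):
            present[code, t] = (code >> t) & 1
    first = np.full(npat, -1)
    last = np.full(npat, -1)
    for code in range(1, npat):
        yrs = np.flatnonzero(present[code])
        first[code], last[code] = yrs[0], yrs[-1]
    gain = np.zeros((npat, T - 1), dtype=np.int64)   # gain at interval (t, t+1)
    loss = np.zeros((npat, T - 1), dtype=np.int64)
    for code in range(1, npat):
        for t1 in range(T - 1):
            gain[code, t1] = int(first[code] == t1 + 1)
            loss[code, t1] = int(last[code] == t1)
    return present, gain, loss


def true_turnover(
    params: SimulationParams,
    group: str = "all",
    n_traps_mc: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected per-trap Gp/Lp for each environment x interval.

    Species-level observed-history probabilities are computed by exact
    enumeration over arrival x persistence x detection outcomes; the
    expectation of the per-trap *ratio* is then taken over Monte-Carlo
    traps whose species patterns are independent draws from those
    probabilities (``n_traps_mc`` per environment).  The trap-level
    fungal resource shared by all fungivores is integrated by
    Gauss-Hermite quadrature (pattern distributions per resource node;
    Monte-Carlo traps draw a node, preserving the within-trap
    correlation it induces).  Traps with zero mean endpoint richness are
    excluded, mirroring the estimator.

    Also reports the expected event counts E[G], E[L] and endpoint
    richness E[S_t1], E[S_t2] (exact, large-pool quantities).
    """
    T = params.n_years
    present, gain, loss = _pattern_stats(T)
    if group == "all":
        affinities = list(params.pool)
    elif group in params.pool:
        affinities = [group]
    else:
        raise ValueError(f"unknown group {group!r}")
    effects = species_effects(params)
    profiles = species_profiles(params, effects)
    sel = effects["host_affinity"].isin(affinities).to_numpy()
    is_fung = (effects["guild"] == "fungivore").to_numpy()
    # Gauss-Hermite nodes for the lognormal trap resource
    gh_x, gh_w = np.polynomial.hermite.hermgauss(15)
    gh_w = gh_w / np.sqrt(np.pi)
    rng = np.random.default_rng(seed)
    rows = []

    def sample_patterns(probs, idx, out_G, out_L, out_S):
        pat = np.searchsorted(
            np.cumsum(probs), rng.random(len(idx)), side="right"
        )
        pat = np.minimum(pat, 2 ** T - 1)
        out_G[idx] += gain[pat]
        out_L[idx] += loss[pat]
        out_S[idx] += present[pat]

    for env_j, env in enumerate(ENVS):
        log_r = (params.fungal_resource_mean[env]
                 + params.fungal_resource_sd * np.sqrt(2.0) * gh_x)
        mults = np.exp(log_r) ** params.fungal_presence_coef
        eg = np.zeros(T - 1)
        el = np.zeros(T - 1)
        es = np.zeros(T)
        G = np.zeros((n_traps_mc, T - 1), dtype=np.int64)
        L = np.zeros((n_traps_mc, T - 1), dtype=np.int64)
        S = np.zeros((n_traps_mc, T), dtype=np.int64)
        node = rng.choice(len(gh_x), size=n_traps_mc, p=gh_w / gh_w.sum())
        node_idx = [np.flatnonzero(node == k) for k in range(len(gh_x))]
        for i in np.flatnonzero(sel):
            base = profiles[i, env_j]
            if is_fung[i]:
                for k, m in enumerate(mults):
                    prof = base * m
                    s = prof.sum()
                    if s > 1.0:
                        prof = prof / s
                    probs = observed_pattern_distribution(
                        prof, params.persistence[env], params.detection, T,
                    )
                    eg += gh_w[k] * (probs @ gain)
                    el += gh_w[k] * (probs @ loss)
                    es += gh_w[k] * (probs @ present)
                    if len(node_idx[k]):
                        sample_patterns(probs, node_idx[k], G, L, S)
            else:
                probs = observed_pattern_distribution(
                    base, params.persistence[env], params.detection, T,
                )
                eg += probs @ gain
                el += probs @ loss
                es += probs @ present
                sample_patterns(probs, np.arange(n_traps_mc), G, L, S)
        for t1 in range(T - 1):
            denom = 0.5 * (S[:, t1] + S[:, t1 + 1])
            ok = denom > 0
            gp = (G[ok, t1] / denom[ok]).mean() if ok.any() else np.nan
            lp = (L[ok, t1] / denom[ok]).mean() if ok.any() else np.nan
            rows.append(dict(
                environment=env, t1=t1 + 1, t2=t1 + 2,
                Gp=gp, Lp=lp,
                E_G=eg[t1], E_L=el[t1],
                E_S_t1=es[t1], E_S_t2=es[t1 + 1],
                n_defined=int(ok.sum()),
            ))
    return pd.DataFrame(rows)
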