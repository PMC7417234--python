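"""Synthetic drone-survey generator.

Emulates the two data products of a thermal-imaging koala survey campaign
with automated detection, together with the latent truth needed for
parameter-recovery and interval-coverage experiments:

* observation tables — per survey, ``true_n`` animals are placed in the
  site, each detected with a covariate-dependent Bernoulli probability
  (logit-linear in ambient temperature and distance to habitat edge);
  detected animals may spawn a duplicate record (probability logit-linear in
  the distance to the nearest other detection, realized from positions);
  false positives arrive as a Poisson count per survey with a habitat-edge
  covariate profile tilted toward small distances;
* transect count arrays — per transect, a latent negative-binomial
  abundance; per visit, binomial availability; available animals are placed
  at a uniform perpendicular distance and detected according to a distance
  key function (uniform or half-normal), then binned.

The default configuration mirrors the scale of the study campaign the
package targets: two sites, 11 surveys (7 training, 4 July test surveys),
roughly 250 training rows, and a 9-transect x 5-visit count array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .survey import TransectCounts, make_survey_id, validate_observations

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_observations",
    "simulate_transect_counts",
    "simulate_bernoulli_design",
]

#: north-site then south-site survey dates; July dates are the test surveys.
DEFAULT_SURVEY_DATES = {
    "north": ("2018-02-10", "2018-03-14", "2018-04-18", "2018-07-10", "2018-07-24"),
    "south": ("2018-02-17", "2018-03-21", "2018-04-25", "2018-05-30", "2018-07-11", "2018-07-25"),
}
DEFAULT_TEST_DATES = ("2018-07-10", "2018-07-11", "2018-07-24", "2018-07-25")


@dataclass
class SimulationConfig:
    """Generating parameters for the synthetic survey campaign.

    Coefficient vectors are on the logit scale: ``p_coefs`` is
    (intercept, temperature, dist_edge) for detection, ``f_coefs``
    (intercept, dist_edge) shapes the habitat-edge profile of false
    positives, ``d_coefs`` (intercept, dist_nearest) governs duplicate
    spawning. Slopes default to the magnitudes a thermal-imaging survey
    plausibly produces (detection falling with temperature and with distance
    into the forest core; false positives concentrated near habitat edges;
    duplicates arising between nearby detections).
    """

    n_sites: int = 2
    survey_dates: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SURVEY_DATES.items()})
    n_visits: int = 5
    transects_per_site: int = 9
    strip_halfwidth: float = 75.0
    # observation-table process
    true_n_mean: float = 15.0
    true_n_dispersion: float | None = None  # None -> Poisson counts of animals per survey
    true_n_per_survey: tuple | None = None  # explicit per-survey counts override
    p_coefs: tuple = (6.5, -0.1879, -0.0233)
    f_rate: float = 11.5
    f_coefs: tuple = (1.0, -0.0324)
    d_coefs: tuple = (0.0, -0.0228)
    temperature_range: tuple = (5.0, 25.0)
    wind_range: tuple = (0.0, 20.0)
    dist_edge_range: tuple = (0.0, 200.0)
    site_extent: tuple = (300.0, 300.0)  # metres; two flight lines 150 m apart
    duplicate_jitter: float = 30.0
    flight_duration: float = 1800.0  # seconds
    # transect-count process
    lambda_coefs: tuple = (3.4, -0.0985, -0.0308)  # log link: intercept, road %, grass %
    phi_coefs: tuple = (0.847,)  # logit link: intercept (availability ~ 0.7)
    nb_dispersion: float = 3.0
    keyfun: str = "uniform"
    halfnormal_sigma: float = 40.0
    landcover_alpha: tuple = (6.0, 3.0, 0.6, 0.4)  # Dirichlet weights: forest, grass, road, water
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_visits < 1 or self.transects_per_site < 1:
            raise ValueError("n_sites, n_visits and transects_per_site must all be >= 1")
        if self.strip_halfwidth <= 0:
            raise ValueError("strip_halfwidth must be positive")
        if self.keyfun not in ("uniform", "halfnormal"):
            raise ValueError(f"unknown key function {self.keyfun!r}")
        # degenerate-config guard: detection impossible over the whole covariate range
        b0, bt, be = self.p_coefs
        corners = [
            b0 + bt * t + be * e
            for t in self.temperature_range
            for e in self.dist_edge_range
        ]
        if max(expit(c) for c in corners) <= 1e-12:
            raise ValueError("p_coefs imply detection probability 0 everywhere; nothing can be simulated")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulationTruth:
    """Latent truth behind a simulated data product."""

    per_survey: pd.DataFrame  # survey_id, true_n and fate composition (observation product)
    coefficients: dict

    def total(self) -> int:
        col = "true_n" if "true_n" in self.per_survey.columns else "M"
        return int(self.per_survey[col].sum())


def _nearest_distance(xy: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest other point (inf for n=1)."""
    n = len(xy)
    if n < 2:
        return np.full(n, np.inf)
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    return np.sqrt(d2.min(axis=1))


def _survey_counts(config: SimulationConfig, n_surveys: int, rng) -> np.ndarray:
    if config.true_n_per_survey is not None:
        counts = np.asarray(config.true_n_per_survey, dtype=int)
        if len(counts) != n_surveys:
            raise ValueError(f"true_n_per_survey needs {n_surveys} entries, got {len(counts)}")
        return counts
    if config.true_n_dispersion is None:
        return rng.poisson(config.true_n_mean, n_surveys)
    a = config.true_n_dispersion
    return rng.negative_binomial(a, a / (a + config.true_n_mean), n_surveys)


def simulate_observations(config: SimulationConfig | None = None, rng=None):
    """Simulate an observation table for the whole campaign.

    Returns ``(table, truth)`` where the table passes
    :func:`aircount.survey.validate_observations` and the truth records the
    per-survey animal count and fate composition. Identical config and seed
    give identical output.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = rng if rng is not None else config.rng()
    width, height = config.site_extent
    lines = np.arange(config.strip_halfwidth, width, 2 * config.strip_halfwidth)

    surveys = [
        (site, pd.Timestamp(d).date())
        for site, dates in sorted(config.survey_dates.items())
        for d in dates
    ]
    true_n = _survey_counts(config, len(surveys), rng)

    rows, truth_rows = [], []
    for (site, date), n_animals in zip(surveys, true_n):
        survey_id = make_survey_id(site, date)
        temp = rng.uniform(*config.temperature_range)
        wind = rng.uniform(*config.wind_range)

        # animals present, their positions and habitat-edge distances
        xy = np.column_stack([rng.uniform(0, width, n_animals), rng.uniform(0, height, n_animals)])
        dist_edge = rng.uniform(*config.dist_edge_range, n_animals)
        eta_p = config.p_coefs[0] + config.p_coefs[1] * temp + config.p_coefs[2] * dist_edge
        detected = rng.uniform(size=n_animals) < expit(eta_p)

        # false positives: Poisson count, habitat-edge profile tilted by f_coefs
        n_false = rng.poisson(config.f_rate)
        f_edge = _tilted_edge_sample(config, n_false, rng)
        f_xy = np.column_stack([rng.uniform(0, width, n_false), rng.uniform(0, height, n_false)])

        det_xy = np.vstack([xy[detected], f_xy]) if n_false or detected.any() else np.empty((0, 2))
        det_edge = np.concatenate([dist_edge[detected], f_edge])
        det_kind = ["unique_detection"] * int(detected.sum()) + ["false_positive"] * n_false

        # duplicates: spawned off detected animals from realized first-pass positions
        nn = _nearest_distance(det_xy)
        dup_xy, dup_edge, dup_parent = [], [], []
        for i in range(int(detected.sum())):
            eta_d = config.d_coefs[0] + config.d_coefs[1] * nn[i]
            if np.isfinite(nn[i]) and rng.uniform() < expit(eta_d):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0, config.duplicate_jitter)
                pos = det_xy[i] + rad * np.array([math.cos(ang), math.sin(ang)])
                dup_xy.append(np.clip(pos, [0, 0], [width, height]))
                dup_edge.append(det_edge[i])
                dup_parent.append(i)

        all_xy = np.vstack([det_xy, np.asarray(dup_xy).reshape(-1, 2)])
        all_edge = np.concatenate([det_edge, np.asarray(dup_edge, dtype=float)])
        all_kind = det_kind + ["duplicate"] * len(dup_xy)
        n_det = len(all_kind)

        # recorded nearest-detection distance: post hoc over all detected objects
        dist_nearest = _nearest_distance(all_xy)
        dist_nearest[~np.isfinite(dist_nearest)] = float(np.hypot(width, height))
        times = np.sort(rng.uniform(0, config.flight_duration, n_det))
        tsp = np.diff(times, prepend=0.0)
        perp = _perp_distance(all_xy[:, 0], lines, config.strip_halfwidth) if n_det else np.empty(0)

        k = 0
        for i in range(n_det):
            k += 1
            rows.append(
                dict(
                    object_id=f"{survey_id}_obj{k}",
                    survey_id=survey_id,
                    site=site,
                    date=date,
                    klass=all_kind[i],
                    temperature=temp,
                    wind_speed=wind,
                    dist_edge=float(all_edge[i]),
                    dist_nearest=float(dist_nearest[i]),
                    time_since_prev=float(tsp[i]),
                    perp_distance=float(perp[i]),
                )
            )
        for j in np.flatnonzero(~detected):
            k += 1
            rows.append(
                dict(
                    object_id=f"{survey_id}_obj{k}",
                    survey_id=survey_id,
                    site=site,
                    date=date,
                    klass="missed",
                    temperature=temp,
                    wind_speed=wind,
                    dist_edge=float(dist_edge[j]),
                    dist_nearest=np.nan,
                    time_since_prev=np.nan,
                    perp_distance=float(_perp_distance(xy[j : j + 1, 0], lines, config.strip_halfwidth)[0]),
                )
            )
        truth_rows.append(
            dict(
                survey_id=survey_id,
                site=site,
                date=date,
                true_n=int(n_animals),
                n_unique=int(detected.sum()),
                n_missed=int(n_animals - detected.sum()),
                n_false=int(n_false),
                n_duplicate=len(dup_xy),
            )
        )

    table = validate_observations(pd.DataFrame(rows), strip_halfwidth=config.strip_halfwidth)
    truth = SimulationTruth(
        per_survey=pd.DataFrame(truth_rows),
        coefficients=dict(p_coefs=config.p_coefs, f_coefs=config.f_coefs, d_coefs=config.d_coefs),
    )
    return table, truth


def _perp_distance(x: np.ndarray, lines: np.ndarray, halfwidth: float) -> np.ndarray:
    if len(lines) == 0:
        return np.minimum(np.abs(x), halfwidth * (1 - 1e-9))
    d = np.abs(x[:, None] - lines[None, :]).min(axis=1)
    return np.minimum(d, halfwidth * (1 - 1e-9))


def _tilted_edge_sample(config: SimulationConfig, n: int, rng) -> np.ndarray:
    """Habitat-edge distances for false positives, density tilted by f_coefs.

    Rejection sampling from the uniform range with acceptance weight
    proportional to ``expit(f_coefs . [1, edge])``, so a negative slope
    concentrates false positives near habitat edges.
    """
    lo, hi = config.dist_edge_range
    g0, g1 = config.f_coefs
    wmax = max(expit(g0 + g1 * lo), expit(g0 + g1 * hi))
    out = np.empty(0)
    while len(out) < n:
        cand = rng.uniform(lo, hi, max(4 * (n - len(out)), 16))
        acc = rng.uniform(size=len(cand)) < expit(g0 + g1 * cand) / wmax
        out = np.concatenate([out, cand[acc]])
    return out[:n]


def simulate_transect_counts(config: SimulationConfig | None = None, rng=None, n_transects=None):
    """Simulate a distance-binned transect count array.

    Latent transect abundance ``M_t ~ NegBin(mean exp(lambda_coefs . covs),
    dispersion nb_dispersion)``; per visit, ``N_tv ~ Binomial(M_t, phi_v)``
    available animals each receive a uniform perpendicular distance on
    ``(0, strip_halfwidth)`` and are detected with the key-function value at
    that distance, then binned into five distance classes.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = rng if rng is not None else config.rng()
    T = int(n_transects or config.transects_per_site)
    V = config.n_visits
    W = config.strip_halfwidth
    edges = np.linspace(0, W, 6)

    landcover = rng.dirichlet(config.landcover_alpha, T) * 100.0
    tcov = pd.DataFrame(landcover, columns=["forest", "grass", "road", "water"])
    vcov = pd.DataFrame(
        {
            "temperature": rng.uniform(*config.temperature_range, V),
            "wind_speed": rng.uniform(*config.wind_range, V),
        }
    )

    lam = np.exp(
        config.lambda_coefs[0]
        + config.lambda_coefs[1] * tcov["road"].to_numpy()
        + config.lambda_coefs[2] * tcov["grass"].to_numpy()
    )
    a = config.nb_dispersion
    M = rng.negative_binomial(a, a / (a + lam)) if np.isfinite(a) else rng.poisson(lam)

    phi_eta = np.full(V, config.phi_coefs[0], dtype=float)
    if len(config.phi_coefs) > 1:
        phi_eta = phi_eta + config.phi_coefs[1] * vcov["temperature"].to_numpy()
    if len(config.phi_coefs) > 2:
        phi_eta = phi_eta + config.phi_coefs[2] * vcov["wind_speed"].to_numpy()
    phi = expit(phi_eta)

    counts = np.zeros((T, V, 5), dtype=int)
    for t in range(T):
        for v in range(V):
            n_avail = rng.binomial(M[t], phi[v])
            if n_avail == 0:
                continue
            x = rng.uniform(0, W, n_avail)
            if config.keyfun == "halfnormal":
                keep = rng.uniform(size=n_avail) < np.exp(-(x**2) / (2 * config.halfnormal_sigma**2))
                x = x[keep]
            counts[t, v, :] = np.histogram(x, bins=edges)[0]

    data = TransectCounts(counts, edges, transect_covs=tcov, visit_covs=vcov, site="synthetic")
    truth = SimulationTruth(
        per_survey=pd.DataFrame({"transect": list(data.transect_ids), "M": M, "lambda": lam}),
        coefficients=dict(
            lambda_coefs=config.lambda_coefs,
            phi_coefs=config.phi_coefs,
            nb_dispersion=config.nb_dispersion,
            keyfun=config.keyfun,
            halfnormal_sigma=config.halfnormal_sigma,
        ),
    )
    return data, truth


#: covariates the coefficient slopes refer to, per model role
ROLE_SLOPE_COVARIATES = {
    "detection": ("temperature", "dist_edge"),
    "false": ("dist_edge",),
    "duplicate": ("dist_nearest",),
}


def simulate_bernoulli_design(
    role: str, n: int, coefs, config: SimulationConfig | None = None, rng=None, covariates=None
):
    """Draw (y, X) directly from one of the three Bernoulli models.

    Covariates are sampled uniformly from the configured ranges and the
    response is Bernoulli with logit-linear probability
    ``coefs . [1, covariates]`` where *covariates* defaults to the slope
    order of the matching generator dial (``p_coefs``/``f_coefs``/
    ``d_coefs``). This is the generating process under which fitted
    coefficients are exactly comparable to the dials, and is what
    parameter-recovery checks use; the full campaign generator in
    :func:`simulate_observations` produces the covariate profiles only
    approximately (see docs/methods.md).
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else config.rng()
    if role in ("detection", "false"):
        X = pd.DataFrame(
            {
                "temperature": rng.uniform(*config.temperature_range, n),
                "wind_speed": rng.uniform(*config.wind_range, n),
                "dist_edge": rng.uniform(*config.dist_edge_range, n),
            }
        )
    elif role == "duplicate":
        X = pd.DataFrame(
            {
                "dist_nearest": rng.uniform(0, 150.0, n),
                "time_since_prev": rng.uniform(0, config.flight_duration, n),
            }
        )
    else:
        raise ValueError(f"unknown role {role!r}")
    coefs = np.asarray(coefs, dtype=float)
    cols = list(covariates) if covariates is not None else list(ROLE_SLOPE_COVARIATES[role])
    if len(cols) != len(coefs) - 1:
        raise ValueError(f"{len(coefs)} coefficients need {len(coefs) - 1} covariates, got {cols}")
    eta = coefs[0] + X[cols].to_numpy() @ coefs[1:]
    y = (rng.uniform(size=n) < expit(eta)).astype(int)
    return y, X


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["survey_dates"] = {k: list(v) for k, v in d["survey_dates"].items()}
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "survey_dates" in d:
        d["survey_dates"] = {k: tuple(v) for k, v in d["survey_dates"].items()}
    for key in ("p_coefs", "f_coefs", "d_coefs", "lambda_coefs", "phi_coefs",
                "temperature_range", "wind_range", "dist_edge_range", "site_extent",
                "landcover_alpha", "true_n_per_survey"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
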